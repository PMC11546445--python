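"""SMOTE geometry/provenance, undersampling, subject-aware splits and folds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgnet import datasplit as ds
from ppgnet.errors import ValidationError
from ppgnet.io import LABELS, DatasetManifest


def _vectors(counts, dim=20, seed=0):
    rng = np.random.default_rng(seed)
    vecs, labels = [], []
    for cls, n in enumerate(counts):
        vecs.append(rng.normal(loc=cls * 5.0, size=(n, dim)))
        labels += [cls] * n
    return np.vstack(vecs), np.array(labels)


def _dist_to_segment(p, a, b):
    ab = b - a
    denom = np.dot(ab, ab)
    t = 0.0 if denom == 0 else np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


class TestSmote:
    def test_balances_study_counts_to_target(self):
        # class sizes before balancing -> all classes at the 250 target
        vecs, labels = _vectors([240, 255, 102, 60])
        v, l, src, syn = ds.balance_classes(vecs, labels, ds.BalanceSpec(250, seed=1))
        assert [int((l == c).sum()) for c in range(4)] == [250, 250, 250, 250]
        assert syn.sum() == (250 - 240) + 0 + (250 - 102) + (250 - 60)

    def test_class_at_target_unchanged(self):
        vecs, labels = _vectors([250, 40])
        v, l, src, syn = ds.smote_oversample(vecs, labels, ds.BalanceSpec(250, seed=0))
        assert int((l == 0).sum()) == 250
        np.testing.assert_array_equal(v[l == 0], vecs[labels == 0])

    def test_synthetic_vectors_lie_on_parent_neighbor_segments(self):
        vecs, labels = _vectors([30, 12], dim=6, seed=3)
        spec = ds.BalanceSpec(30, smote_k=5, seed=7)
        v, l, src, syn = ds.smote_oversample(vecs, labels, spec)
        minority = vecs[labels == 1]
        for p in v[syn]:
            d = min(
                _dist_to_segment(p, minority[i], minority[j])
                for i in range(len(minority))
                for j in range(len(minority))
                if i != j
            )
            assert d < 1e-9

    def test_synthetic_inherits_source_subject(self):
        vecs, labels = _vectors([10, 4])
        srcs = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(4)]
        _, l, out_src, syn = ds.smote_oversample(
            vecs, labels, ds.BalanceSpec(10, seed=0), srcs
        )
        for s, is_syn, lab in zip(out_src, syn, l):
            if is_syn:
                assert lab == 1 and s.startswith("B")

    def test_singleton_minority_rejected(self):
        vecs, labels = _vectors([5, 1])
        with pytest.raises(ValidationError, match="interpolate"):
            ds.smote_oversample(vecs, labels, ds.BalanceSpec(5, seed=0))

    def test_deterministic(self):
        vecs, labels = _vectors([20, 8])
        a = ds.smote_oversample(vecs, labels, ds.BalanceSpec(20, seed=5))
        b = ds.smote_oversample(vecs, labels, ds.BalanceSpec(20, seed=5))
        np.testing.assert_array_equal(a[0], b[0])


class TestUndersample:
    def test_255_to_250_all_originals(self):
        vecs, labels = _vectors([255])
        v, l, kept = ds.undersample(vecs, labels, 250, seed=2)
        assert v.shape[0] == 250
        assert len(set(map(tuple, v))) == 250  # no duplicates
        orig = set(map(tuple, vecs))
        assert all(tuple(row) in orig for row in v)

    def test_target_equals_count_identity(self):
        vecs, labels = _vectors([10])
        v, l, kept = ds.undersample(vecs, labels, 10, seed=0)
        np.testing.assert_array_equal(v, vecs)

    def test_same_seed_same_subset(self):
        vecs, labels = _vectors([50])
        a = ds.undersample(vecs, labels, 20, seed=9)[2]
        b = ds.undersample(vecs, labels, 20, seed=9)[2]
        np.testing.assert_array_equal(a, b)


def _manifest(n_subjects, segs=3, synthetic_of=None, seed=0):
    rows = []
    rng = np.random.default_rng(seed)
    for s in range(n_subjects):
        lab = LABELS[int(rng.integers(4))]
        for g in range(segs):
            rows.append((f"p{s}_{g}", f"S{s}", lab, g, False, f"S{s}"))
    if synthetic_of is not None:
        for i, parent in enumerate(synthetic_of):
            rows.append((f"syn{i}", f"{parent}:syn{i}", "S1", 0, True, parent))
    return DatasetManifest(pd.DataFrame(rows, columns=[
        "path", "subject_id", "label", "segment_index", "synthetic", "source_subject_id"
    ]))


class TestSubjectAwareSplit:
    def test_fraction_and_no_overlap(self):
        plan = ds.subject_aware_split(_manifest(10), 0.2, seed=4)
        assert len(plan.test_subjects) == 2
        assert not set(plan.test_subjects) & set(plan.train_subjects)

    def test_zero_fraction_empty_test(self):
        plan = ds.subject_aware_split(_manifest(8), 0.0, seed=0)
        assert plan.test_subjects == []

    def test_synthetic_children_follow_parent(self):
        m = _manifest(10, synthetic_of=["S3", "S7", "S3"])
        plan = ds.subject_aware_split(m, 0.3, seed=1)
        for side in (plan.test_subjects, plan.train_subjects):
            rows = m.df[m.df["source_subject_id"].isin(side)]
            # every synthetic row's parent is on the same side
            assert set(rows[rows["synthetic"]]["source_subject_id"]) <= set(side)

    def test_deterministic(self):
        a = ds.subject_aware_split(_manifest(20), 0.2, seed=3)
        b = ds.subject_aware_split(_manifest(20), 0.2, seed=3)
        assert a.to_dict() == b.to_dict()

    @settings(max_examples=200, deadline=None)
    @given(
        n_subjects=st.integers(5, 40),
        n_syn=st.integers(0, 10),
        seed=st.integers(0, 10_000),
        frac=st.floats(0.0, 0.5),
    )
    def test_leakage_guard_property(self, n_subjects, n_syn, seed, frac):
        """For any manifest (with synthetic records attached to random
        parents), source subjects never straddle the split."""
        rng = np.random.default_rng(seed)
        parents = [f"S{int(rng.integers(n_subjects))}" for _ in range(n_syn)]
        m = _manifest(n_subjects, synthetic_of=parents, seed=seed)
        plan = ds.subject_aware_split(m, frac, seed=seed)
        tr = m.df[m.df["source_subject_id"].isin(plan.train_subjects)]
        te = m.df[m.df["source_subject_id"].isin(plan.test_subjects)]
        assert not (set(tr["source_subject_id"]) & set(te["source_subject_id"]))
        assert len(tr) + len(te) == len(m)  # every record follows its subject


class TestKFold:
    def test_25_subjects_five_equal_folds(self):
        folds = ds.kfold_plan([f"S{i}" for i in range(25)], 5, seed=0)
        assert [len(f) for f in folds] == [5] * 5

    def test_26_subjects_sizes(self):
        folds = ds.kfold_plan([f"S{i}" for i in range(26)], 5, seed=0)
        assert sorted(len(f) for f in folds) == [5, 5, 5, 5, 6]

    def test_partition_property(self):
        subjects = [f"S{i}" for i in range(17)]
        folds = ds.kfold_plan(subjects, 5, seed=2)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(subjects)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            ds.kfold_plan(["a", "b"], 5, seed=0)


class TestSplitPlan:
    def test_json_round_trip(self, tmp_path):
        plan = ds.SplitPlan(["S1"], ["S2", "S3", "S4", "S5", "S6"],
                            [["S2"], ["S3"], ["S4"], ["S5"], ["S6"]])
        d = plan.to_dict()
        assert ds.SplitPlan.from_dict(d).to_dict() == d

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ValidationError):
            ds.SplitPlan(["S1"], ["S1", "S2"])

    def test_bad_folds_rejected(self):
        with pytest.raises(ValidationError):
            ds.SplitPlan(["S1"], ["S2", "S3"], [["S2"], ["S2", "S3"]])
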