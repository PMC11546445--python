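"""Class balancing (SMOTE + undersampling) and subject-aware evaluation splits.

Balancing operates on equal-length signal vectors *before* scalogram
rendering: SMOTE interpolation in signal space yields valid pulse trains
whose scalograms can be recomputed, whereas pixel-space interpolation of
rendered images is physically meaningless.

Every synthetic vector inherits the ``source_subject_id`` of the record it
was interpolated from, and splits group by that id — so a subject's
synthetic derivatives can never sit on the other side of a train/test
boundary from their parent (the leakage guard).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .io import DatasetManifest

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BalanceSpec:
    """Target per-class count and SMOTE neighborhood size."""

    per_class_target: int = 250
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class_target < 1:
            raise ValidationError("per_class_target must be >= 1")
        if self.smote_k < 1:
            raise ValidationError("smote_k must be >= 1")


@dataclasses.dataclass
class SplitPlan:
    """Subject-level assignment to train/test and to k folds of train."""

    test_subjects: list[str]
    train_subjects: list[str]
    folds: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if set(self.test_subjects) & set(self.train_subjects):
            raise ValidationError("test and train subject sets overlap")
        if self.folds is not None:
            flat = [s for fold in self.folds for s in fold]
            if len(flat) != len(set(flat)):
                raise ValidationError("folds are not pairwise disjoint")
            if set(flat) != set(self.train_subjects):
                raise ValidationError("folds must partition train_subjects exactly")

    def to_dict(self) -> dict:
        return {
            "test_subjects": list(self.test_subjects),
            "train_subjects": list(self.train_subjects),
            "folds": None if self.folds is None else [list(f) for f in self.folds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(d["test_subjects"], d["train_subjects"], d.get("folds"))


def smote_oversample(
    vectors: np.ndarray,
    labels: np.ndarray,
    spec: BalanceSpec,
    source_subject_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """SMOTE each minority class up to ``spec.per_class_target``.

    New vectors are x + lambda * (x_nn - x) with lambda ~ U[0, 1] and x_nn
    one of the ``smote_k`` Euclidean nearest same-class neighbors of x.
    Returns (vectors, labels, source_subject_ids, synthetic_mask) with the
    originals first, in input order.

    Classes already at or above the target are passed through unchanged
    (use :func:`undersample` first to bring majority classes down).
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    if vectors.ndim != 2 or vectors.shape[0] != labels.shape[0]:
        raise ValidationError("vectors must be 2-D with one row per label")
    n = vectors.shape[0]
    if source_subject_ids is None:
        source_subject_ids = [f"row{i}" for i in range(n)]
    if len(source_subject_ids) != n:
        raise ValidationError("source_subject_ids length mismatch")
    rng = np.random.default_rng(spec.seed)
    out_v = [vectors]
    out_l = [labels]
    out_src = list(source_subject_ids)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        deficit = spec.per_class_target - idx.size
        if deficit <= 0:
            continue
        if idx.size < 2:
            raise ValidationError(
                f"class {cls!r} has {idx.size} member(s); need >= 2 to interpolate"
            )
        k = min(spec.smote_k, idx.size - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(vectors[idx])
        neigh = nn.kneighbors(vectors[idx], return_distance=False)[:, 1:]
        parents = rng.integers(0, idx.size, size=deficit)
        picks = rng.integers(0, k, size=deficit)
        lams = rng.uniform(0.0, 1.0, size=deficit)
        x = vectors[idx[parents]]
        x_nn = vectors[idx[neigh[parents, picks]]]
        out_v.append(x + lams[:, None] * (x_nn - x))
        out_l.append(np.full(deficit, cls, dtype=labels.dtype))
        out_src.extend(source_subject_ids[idx[p]] for p in parents)
    aug_v = np.vstack(out_v)
    aug_l = np.concatenate(out_l)
    mask = np.zeros(aug_v.shape[0], dtype=bool)
    mask[n:] = True
    return aug_v, aug_l, out_src, mask


def undersample(
    vectors: np.ndarray, labels: np.ndarray, target: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduce every class above ``target`` to exactly ``target`` members.

    Uniform subset without replacement, deterministic given ``seed``.
    Returns (vectors, labels, kept_indices) with original relative order.
    """
    vectors = np.asarray(vectors)
    labels = np.asarray(labels)
    if target < 0:
        raise ValidationError("target must be >= 0")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size > target:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        keep.append(idx)
    kept = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)
    return vectors[kept], labels[kept], kept


def balance_classes(
    vectors: np.ndarray,
    labels: np.ndarray,
    spec: BalanceSpec,
    source_subject_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Undersample majority classes, then SMOTE minorities: every class ends
    at exactly ``spec.per_class_target`` members."""
    v, l, kept = undersample(vectors, labels, spec.per_class_target, spec.seed)
    src = None
    if source_subject_ids is not None:
        src = [source_subject_ids[i] for i in kept]
    return smote_oversample(v, l, spec, src)


def subject_aware_split(
    manifest: DatasetManifest, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Shuffle subjects (grouped by ``source_subject_id``) and hold out
    ``round(test_fraction * n_subjects)`` of them as the test side.

    Records always follow their subject, so synthetic derivatives land on
    the same side as their parent.  A class entirely absent from the
    training side is logged as a warning, not an error.
    """
    if not (0.0 <= test_fraction <= 1.0):
        raise ValidationError("test_fraction must lie in [0, 1]")
    subjects = manifest.subject_ids
    if len(subjects) < 5:
        raise ValidationError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_test = int(round(test_fraction * len(subjects)))
    shuffled = [subjects[i] for i in order]
    test = sorted(shuffled[:n_test])
    train = sorted(shuffled[n_test:])
    train_set = set(train)
    train_labels = set(
        manifest.df.loc[manifest.df["source_subject_id"].isin(train_set), "label"]
    )
    for lab in set(manifest.df["label"]) - train_labels:
        logger.warning("class %s has no records on the training side", lab)
    return SplitPlan(test_subjects=test, train_subjects=train)


def kfold_plan(train_subjects: list[str], k: int = 5, seed: int = 0) -> list[list[str]]:
    """Partition subjects into k folds with sizes differing by at most 1."""
    subjects = list(train_subjects)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(subjects):
        raise ValidationError(f"k={k} exceeds the {len(subjects)} subjects available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    base, extra = divmod(len(subjects), k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(sorted(shuffled[start:start + size]))
        start += size
    return folds


def records_for_subjects(
    manifest: DatasetManifest, subjects: list[str] | set[str]
) -> np.ndarray:
    """Row indices of all records whose source subject is in ``subjects``."""
    s = set(subjects)
    return np.flatnonzero(manifest.df["source_subject_id"].isin(s).to_numpy())


def assert_no_leakage(
    train_sources: list[str] | set[str], test_sources: list[str] | set[str]
) -> None:
    """Raise if any source subject appears on both sides of a split."""
    overlap = set(train_sources) & set(test_sources)
    if overlap:
        raise ValidationError(f"subject leakage across split: {sorted(overlap)[:5]}")
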