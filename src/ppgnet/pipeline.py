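"""End-to-end pipeline: synth -> preprocess -> balance -> scalogram -> split
-> train -> evaluate, driven by one nested config.

The config is a nested mapping (YAML/JSON) whose sections mirror the stage
dataclasses; unknown keys are rejected with the offending key named.  Reruns
with the same config and seed reproduce the manifest, split plan, and
images bit-exactly.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import datasplit, io, metrics, model as model_mod, preprocess, scalogram, synth
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "enabled": True,
        "n_subjects": 40,
        "class_counts": None,  # None -> equal classes at desk scale
        "class_proportions": None,  # overrides class_counts if given
        "fs": 1000.0,
        "segment_seconds": 2.1,
        "segments_per_subject": 3,
        "noise_sd": 0.02,
        "baseline_wander_amp": 0.05,
    },
    "input_manifest": None,  # used when synth.enabled is false
    "preprocess": {
        "wavelet_name": "sym8",
        "levels": None,
        "pass_lo": 0.05,
        "pass_hi": 16.0,
        "numtaps": 1001,
    },
    "scalogram": {
        "omega0": 6.0,
        "voices_per_octave": 12,
        "freq_min": 0.5,
        "freq_max": 32.0,
        "image_size": [64, 64],
        "cmap": "viridis",
    },
    "balance": {
        "mode": "off",  # off | train_only | dataset_wide
        "per_class_target": 250,
        "smote_k": 5,
    },
    "split": {"test_fraction": 0.2, "folds": 5},
    "model": {
        "desk_scale": True,
        "stem_widths": None,
        "entry_widths": None,
        "middle_blocks": None,
        "exit_widths": None,
        "use_batch_normalization": True,
    },
    "train": {
        "learning_rate": 0.01,
        "batch_size": 12,
        "epochs": 20,
        "early_stop_patience": 10,
        "momentum": 0.9,
        # 5-fold CV on the training side; the held-out test set is scored
        # by the fold models' averaged probabilities
        "cross_validate": True,
    },
}


def _merge_strict(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ValidationError(f"unknown config key: {prefix}{key}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_strict(defaults[key], val, prefix=f"{prefix}{key}.")
        else:
            out[key] = val
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    return _merge_strict(DEFAULT_CONFIG, user or {})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_model_cfg(cfg: dict, image_size) -> model_mod.PPGNetConfig:
    m = cfg["model"]
    base = model_mod.PPGNetConfig.desk_scale() if m["desk_scale"] else model_mod.PPGNetConfig()
    kwargs = dataclasses.asdict(base)
    kwargs["input_size"] = (int(image_size[0]), int(image_size[1]), 3)
    for key in ("stem_widths", "entry_widths", "exit_widths"):
        if m[key] is not None:
            kwargs[key] = tuple(m[key])
    if m["middle_blocks"] is not None:
        kwargs["middle_blocks"] = int(m["middle_blocks"])
    kwargs["use_batch_normalization"] = bool(m["use_batch_normalization"])
    for key in ("stem_widths", "entry_widths", "exit_widths", "input_size"):
        kwargs[key] = tuple(kwargs[key])
    return model_mod.PPGNetConfig(**kwargs)


@dataclasses.dataclass
class PipelineResult:
    out_dir: Path
    manifest: io.DatasetManifest
    split_plan: datasplit.SplitPlan
    report: metrics.MetricsReport
    test_accuracy: float
    fold_results: list | None


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/latest") -> PipelineResult:
    """Execute every stage and write all artifacts under ``out_dir``.

    Artifacts: cohort manifest + signal files, preprocessed vectors,
    scalogram PNGs + image manifest, split plan JSON, trained weights
    (.npz + JSON sidecar), metrics report (JSON + aligned text), and a run
    log with the config hash and seed.
    """
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- stage 1: cohort -------------------------------------------------
    if cfg["synth"]["enabled"]:
        s = cfg["synth"]
        if s["class_proportions"] is not None:
            scfg = synth.SynthCohortConfig(
                n_subjects=int(s["n_subjects"]),
                class_proportions=tuple(s["class_proportions"]),
                fs=s["fs"], segment_seconds=s["segment_seconds"],
                segments_per_subject=int(s["segments_per_subject"]),
                noise_sd=s["noise_sd"], baseline_wander_amp=s["baseline_wander_amp"],
                seed=seed,
            )
        elif s["class_counts"] is not None:
            scfg = synth.SynthCohortConfig(
                n_subjects=int(s["n_subjects"]), class_counts=tuple(s["class_counts"]),
                fs=s["fs"], segment_seconds=s["segment_seconds"],
                segments_per_subject=int(s["segments_per_subject"]),
                noise_sd=s["noise_sd"], baseline_wander_amp=s["baseline_wander_amp"],
                seed=seed,
            )
        else:
            scfg = dataclasses.replace(
                synth.desk_scale_config(seed=seed, n_subjects=int(s["n_subjects"])),
                fs=s["fs"], segment_seconds=s["segment_seconds"],
                segments_per_subject=int(s["segments_per_subject"]),
                noise_sd=s["noise_sd"], baseline_wander_amp=s["baseline_wander_amp"],
            )
        manifest, records = synth.generate_cohort(scfg, out_dir=out / "cohort")
        fs = scfg.fs
    else:
        if not cfg["input_manifest"]:
            raise ValidationError("synth disabled and no input_manifest given")
        manifest = io.read_manifest(cfg["input_manifest"])
        root = Path(cfg["input_manifest"]).parent
        records = []
        for row in manifest.rows():
            x = io.read_signal(root / row["path"])
            records.append(
                io.PPGRecord(row["subject_id"], row["label"], int(row["segment_index"]),
                             x, cfg["synth"]["fs"], bool(row["synthetic"]),
                             row["source_subject_id"])
            )
        fs = cfg["synth"]["fs"]
    if not records:
        raise ValidationError("stage synth: empty cohort")
    logger.info("cohort: %d records, %d subjects", len(manifest), len(manifest.subject_ids))

    # --- stage 2: preprocess ---------------------------------------------
    p = cfg["preprocess"]
    fspec = preprocess.FilterSpec(fs=fs, pass_lo=p["pass_lo"], pass_hi=p["pass_hi"],
                                  numtaps=int(p["numtaps"]))
    dspec = preprocess.DenoiseSpec(wavelet_name=p["wavelet_name"], levels=p["levels"])
    kernel = preprocess.design_remez_bandpass(fspec)
    vectors = np.stack([
        preprocess.preprocess_segment(r.samples, dspec, coefficients=kernel)
        for r in records
    ])
    labels = np.array([r.label_code for r in records])
    sources = [r.source_subject_id for r in records]
    synthetic_mask = np.array([r.synthetic for r in records])

    # --- stage 3: split ---------------------------------------------------
    sp = cfg["split"]
    plan = datasplit.subject_aware_split(manifest, float(sp["test_fraction"]), seed)
    plan.folds = datasplit.kfold_plan(plan.train_subjects, int(sp["folds"]), seed)
    io.write_json(plan.to_dict(), out / "split_plan.json")
    train_set, test_set = set(plan.train_subjects), set(plan.test_subjects)
    datasplit.assert_no_leakage(train_set, test_set)

    # --- stage 4: balance (training side only, or dataset-wide) -----------
    b = cfg["balance"]
    if b["mode"] not in ("off", "train_only", "dataset_wide"):
        raise ValidationError(f"unknown balance mode {b['mode']!r}")
    if b["mode"] != "off":
        spec = datasplit.BalanceSpec(int(b["per_class_target"]), int(b["smote_k"]), seed)
        if b["mode"] == "train_only":
            tr = np.array([s in train_set for s in sources])
            v, l, src, syn = datasplit.balance_classes(
                vectors[tr], labels[tr], spec, [s for s, m in zip(sources, tr) if m]
            )
            vectors = np.vstack([v, vectors[~tr]])
            labels = np.concatenate([l, labels[~tr]])
            sources = src + [s for s, m in zip(sources, ~tr) if m]
            synthetic_mask = np.concatenate([syn, np.array([False] * int((~tr).sum()))])
        else:  # dataset-wide bookkeeping (reproduces the reference class counts)
            vectors, labels, sources, synthetic_mask = datasplit.balance_classes(
                vectors, labels, spec, sources
            )

    # --- stage 5: scalogram images ----------------------------------------
    sc = cfg["scalogram"]
    cwt_cfg = scalogram.CWTConfig(
        omega0=sc["omega0"], voices_per_octave=int(sc["voices_per_octave"]),
        freq_min=sc["freq_min"], freq_max=sc["freq_max"], fs=fs,
    )
    bank = scalogram.MorletFilterBank(cwt_cfg)
    hw = (int(sc["image_size"][0]), int(sc["image_size"][1]))
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    images = np.empty((len(vectors), hw[0], hw[1], 3), dtype=np.uint8)
    for i, v in enumerate(vectors):
        images[i] = scalogram.render_scalogram(bank.transform(v), hw, sc["cmap"])
        io.write_scalogram_image(images[i], img_dir / f"seg{i:05d}.png")
    x_all = images.astype(np.float32) / 255.0

    # --- stage 6: train ----------------------------------------------------
    model_cfg = _build_model_cfg(cfg, hw)
    t = cfg["train"]
    tcfg = model_mod.TrainConfig(
        learning_rate=t["learning_rate"], batch_size=int(t["batch_size"]),
        epochs=int(t["epochs"]), folds=int(sp["folds"]),
        early_stop_patience=int(t["early_stop_patience"]),
        momentum=t["momentum"], seed=seed,
    )
    src_arr = np.asarray(sources)
    tr_mask = np.isin(src_arr, list(train_set))
    te_mask = np.isin(src_arr, list(test_set)) & ~synthetic_mask  # test on real records
    fold_results = None
    if t["cross_validate"]:
        fold_results, models = model_mod.train_cv(
            model_cfg, x_all[tr_mask], labels[tr_mask],
            [s for s, m in zip(sources, tr_mask) if m], plan.folds, tcfg,
        )
        accs = [r.val_accuracy for r in fold_results]
        logger.info("cv accuracy: %.3f +/- %.3f", np.mean(accs), np.std(accs))
        for i, m in enumerate(models):
            model_mod.save_model(m, out / f"weights_fold{i}.npz", seed=seed)
        net = models[int(np.argmax(accs))]
    else:
        # validation = first fold's subjects; train = remaining folds
        val_subj = set(plan.folds[0])
        val_mask = tr_mask & np.isin(src_arr, list(val_subj))
        fit_mask = tr_mask & ~val_mask
        net = model_mod.build_ppgnet(model_cfg, seed=seed)
        model_mod.fit(net, x_all[fit_mask], labels[fit_mask],
                      x_all[val_mask], labels[val_mask], tcfg)
        models = [net]
    model_mod.save_model(net, out / "weights.npz", seed=seed)

    # --- stage 7: evaluate --------------------------------------------------
    # average fold probabilities (single-model list when CV is off)
    probs = np.mean([model_mod.predict(m, x_all[te_mask])[1] for m in models], axis=0)
    y_pred = probs.argmax(axis=1)
    cm = metrics.confusion_matrix(labels[te_mask], y_pred)
    report = metrics.metrics_report(cm)
    io.write_json(report.to_dict(), out / "metrics.json")
    (out / "metrics.txt").write_text(report.format_table() + "\n")
    io.write_json(
        {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 2),
            "n_records": int(len(manifest)),
            "test_accuracy": report.overall_accuracy,
        },
        out / "run_meta.json",
    )
    logger.info("held-out test accuracy: %.3f", report.overall_accuracy)
    return PipelineResult(out, manifest, plan, report, report.overall_accuracy, fold_results)
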