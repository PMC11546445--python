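"""Seeded synthetic PPG cohort generator.

Emulates the acquisition design the pipeline targets: per subject, three
2.1-s finger-PPG segments sampled at 1000 Hz, one of four blood-pressure
stage labels (N, P, S1, S2), and a skewness signal-quality gate — a segment
is only emitted if its sample skewness exceeds zero, mirroring how the real
recordings were saved.

Each beat is a two-Gaussian waveform: a systolic peak plus a delayed,
scaled dicrotic bump, with per-beat period jitter, sinusoidal baseline
wander, and white noise.  The default per-class morphologies form a
monotone gradient (decreasing dicrotic-notch amplitude, rising heart rate,
narrowing systolic width, N -> S2).  They are test fixtures that give the
downstream classifier a learnable, physiologically flavored signal — not
claims about hypertension physiology.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import GenerationError, ValidationError
from .io import LABELS, DatasetManifest, PPGRecord, write_signal
from .preprocess import skewness_sqi

#: Default subject proportions follow the study design the generator
#: emulates: per-class segment counts 240/255/102/60 over 657 segments
#: (3 per subject) give subject counts 80/85/34/20 of 219.
DEFAULT_CLASS_PROPORTIONS: tuple[float, float, float, float] = (
    80 / 219,
    85 / 219,
    34 / 219,
    20 / 219,
)


@dataclasses.dataclass
class ClassMorphology:
    """Per-class pulse-shape parameters.

    heart_rate_range : (lo, hi) bpm interval subjects of the class draw from
    systolic_width   : Gaussian sigma of the systolic peak, seconds
    notch_amplitude  : dicrotic bump height as a fraction of the systolic peak
    reflection_delay : systolic-peak-to-dicrotic-bump delay, seconds
    amplitude_jitter : per-beat amplitude jitter fraction
    """

    heart_rate_range: tuple[float, float]
    systolic_width: float
    notch_amplitude: float
    reflection_delay: float
    amplitude_jitter: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.heart_rate_range
        if not (40.0 <= lo <= hi <= 180.0):
            raise ValidationError("heart_rate_range must lie within [40, 180] bpm")
        for name in ("notch_amplitude", "amplitude_jitter"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.systolic_width <= 0 or self.reflection_delay <= 0:
            raise ValidationError("systolic_width and reflection_delay must be > 0")


#: Monotone morphology gradient across stages (fixtures, not physiology).
#: Heart-rate ranges are center +/- 3 bpm and pairwise disjoint, so the
#: default cohort has well-separated classes by construction.
DEFAULT_MORPHOLOGIES: dict[str, ClassMorphology] = {
    "N": ClassMorphology((62, 68), 0.055, 0.50, 0.30),
    "P": ClassMorphology((69, 75), 0.048, 0.35, 0.28),
    "S1": ClassMorphology((77, 83), 0.042, 0.20, 0.26),
    "S2": ClassMorphology((85, 91), 0.037, 0.10, 0.24),
}


@dataclasses.dataclass
class SynthCohortConfig:
    """Cohort-level design: sizes, rates, noise, and the seed.

    ``class_proportions`` are converted to integer subject counts by the
    largest-remainder rule; pass ``class_counts`` to fix them exactly.
    """

    n_subjects: int = 219
    class_proportions: tuple[float, float, float, float] = DEFAULT_CLASS_PROPORTIONS
    class_counts: tuple[int, int, int, int] | None = None
    fs: float = 1000.0
    segment_seconds: float = 2.1
    segments_per_subject: int = 3
    noise_sd: float = 0.02
    baseline_wander_amp: float = 0.05
    baseline_wander_freq: float = 0.25
    seed: int = 0
    max_sqi_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.segments_per_subject < 0:
            raise ValidationError("counts must be >= 0")
        if self.noise_sd < 0 or self.baseline_wander_amp < 0:
            raise ValidationError("noise_sd and baseline_wander_amp must be >= 0")
        if self.class_counts is not None:
            if len(self.class_counts) != 4 or any(c < 0 for c in self.class_counts):
                raise ValidationError("class_counts must be 4 nonnegative integers")
            if sum(self.class_counts) != self.n_subjects:
                raise ValidationError("class_counts must sum to n_subjects")
        else:
            if len(self.class_proportions) != 4 or any(p < 0 for p in self.class_proportions):
                raise ValidationError("class_proportions must be 4 nonnegative reals")
            if abs(sum(self.class_proportions) - 1.0) > 1e-9:
                raise ValidationError("class_proportions must sum to 1 (within 1e-9)")

    def resolved_class_counts(self) -> tuple[int, int, int, int]:
        """Integer subjects per class (largest-remainder apportionment)."""
        if self.class_counts is not None:
            return tuple(self.class_counts)
        quotas = np.array(self.class_proportions) * self.n_subjects
        counts = np.floor(quotas).astype(int)
        rem = self.n_subjects - counts.sum()
        order = np.argsort(-(quotas - counts))  # ties -> lower class index first
        counts[order[:rem]] += 1
        return tuple(int(c) for c in counts)


def generate_pulse_train(
    morph: ClassMorphology,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
    baseline_wander_freq: float = 0.25,
    heart_rate_bpm: float | None = None,
    phase_offset: float | None = None,
    period_jitter: float = 0.03,
) -> np.ndarray:
    """Generate one quasi-periodic PPG-like pulse train.

    Beats are laid down from ``-phase_offset`` with per-beat period jitter
    (uniform ±``period_jitter``); each beat contributes a systolic Gaussian
    and a delayed dicrotic Gaussian (width 0.6x systolic) scaled by
    ``notch_amplitude``.  Deterministic given the generator state.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    hr = heart_rate_bpm if heart_rate_bpm is not None else rng.uniform(*morph.heart_rate_range)
    period = 60.0 / hr
    if phase_offset is None:
        phase_offset = rng.uniform(0.0, period)
    x = np.zeros(n)
    w = morph.systolic_width
    # Start one beat early and run one beat past the end so edge beats
    # contribute their tails.
    t_peak = -phase_offset - period
    while t_peak < duration + period:
        amp = 1.0 + morph.amplitude_jitter * rng.uniform(-1.0, 1.0)
        x += amp * np.exp(-((t - t_peak) ** 2) / (2.0 * w**2))
        x += (
            amp
            * morph.notch_amplitude
            * np.exp(-((t - t_peak - morph.reflection_delay) ** 2) / (2.0 * (0.6 * w) ** 2))
        )
        t_peak += period * (1.0 + period_jitter * rng.uniform(-1.0, 1.0))
    if baseline_wander_amp > 0:
        x += baseline_wander_amp * np.sin(
            2.0 * np.pi * baseline_wander_freq * t + rng.uniform(0.0, 2.0 * np.pi)
        )
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return x


def class_prototype(label: str, duration: float = 2.1, fs: float = 1000.0) -> np.ndarray:
    """Noiseless, jitter-free waveform of a class at its center heart rate.

    Used by tests and docs to show that default morphologies are pairwise
    distinguishable.
    """
    morph = DEFAULT_MORPHOLOGIES[label]
    rng = np.random.default_rng(0)  # unused draws (jitter disabled)
    hr = 0.5 * (morph.heart_rate_range[0] + morph.heart_rate_range[1])
    m = dataclasses.replace(morph, amplitude_jitter=0.0)
    return generate_pulse_train(
        m, duration, fs, rng, heart_rate_bpm=hr, phase_offset=0.3, period_jitter=0.0
    )


def generate_cohort(
    config: SynthCohortConfig,
    morphologies: dict[str, ClassMorphology] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[PPGRecord]]:
    """Generate a labeled cohort; optionally write signal files + manifest.

    Subjects are assigned classes per the configured proportions; each
    contributes ``segments_per_subject`` segments.  The beat-phase offset of
    a segment is resampled (bounded retries) until the segment passes the
    skewness-SQI gate, mirroring the acquisition saving rule.  Identical
    config (and seed) reproduces the cohort bit-exactly.
    """
    morphologies = morphologies or DEFAULT_MORPHOLOGIES
    rng = np.random.default_rng(config.seed)
    counts = config.resolved_class_counts()
    records: list[PPGRecord] = []
    paths: list[str] = []
    width = max(4, len(str(max(config.n_subjects, 1))))
    sidx = 0
    for label, count in zip(LABELS, counts):
        morph = morphologies[label]
        for _ in range(count):
            subject_id = f"S{sidx:0{width}d}"
            sidx += 1
            hr = rng.uniform(*morph.heart_rate_range)
            for seg in range(config.segments_per_subject):
                for attempt in range(config.max_sqi_retries):
                    x = generate_pulse_train(
                        morph,
                        config.segment_seconds,
                        config.fs,
                        rng,
                        noise_sd=config.noise_sd,
                        baseline_wander_amp=config.baseline_wander_amp,
                        baseline_wander_freq=config.baseline_wander_freq,
                        heart_rate_bpm=hr,
                    )
                    if skewness_sqi(x) > 0:
                        break
                else:
                    raise GenerationError(
                        f"class {label}: segment failed the skewness gate "
                        f"{config.max_sqi_retries} times"
                    )
                records.append(
                    PPGRecord(subject_id, label, seg, x, config.fs)
                )
                paths.append(f"signals/{subject_id}_seg{seg}.csv")
    manifest = DatasetManifest.from_records(records, paths) if records else DatasetManifest(
        _empty_frame()
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "signals").mkdir(parents=True, exist_ok=True)
        for rec, rel in zip(records, paths):
            write_signal(rec.samples, out / rel)
        from .io import write_manifest

        write_manifest(manifest, out / "manifest.csv")
    return manifest, records


def _empty_frame():
    import pandas as pd

    from .io import MANIFEST_COLUMNS

    return pd.DataFrame({c: [] for c in MANIFEST_COLUMNS})


def desk_scale_config(seed: int = 0, n_subjects: int = 40) -> SynthCohortConfig:
    """Small balanced cohort for CPU-scale end-to-end runs (equal classes)."""
    base = n_subjects // 4
    counts = [base] * 4
    for i in range(n_subjects - 4 * base):
        counts[i] += 1
    return SynthCohortConfig(
        n_subjects=n_subjects, class_counts=tuple(counts), seed=seed
    )
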