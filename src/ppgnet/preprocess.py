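"""PPG signal conditioning: wavelet denoising, equiripple FIR bandpass,
min-max normalization, the skewness signal-quality gate, and segmentation.

The conditioning chain is denoise -> bandpass -> normalize; each step
preserves segment length, and the final output lies in [0, 1].

The bandpass is an equiripple (Parks-McClellan / Remez) linear-phase FIR
with a 0.05-16 Hz passband, covering heart-rate and respiratory content
while rejecting high-frequency noise.  At the default 1001 taps and
fs = 1000 Hz the sub-0.05 Hz edge cannot be realized (it would need on the
order of 1e5 taps), so the lower stopband is down-weighted and the filter's
effective action on short segments is the 16 Hz lowpass; DC gain is ~0.97,
which is immaterial because min-max normalization follows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt
from scipy import signal as _signal

from .errors import DegenerateSegmentError, FilterDesignError, ValidationError


@dataclasses.dataclass
class FilterSpec:
    """Equiripple FIR bandpass design parameters.

    ``weights`` are the Remez error weights for (lower stop, pass, upper
    stop).  The small default lower-stop weight concentrates the equiripple
    error budget on the passband and the realizable upper stopband.
    """

    fs: float = 1000.0
    pass_lo: float = 0.05
    pass_hi: float = 16.0
    stop_lo: float = 0.01
    stop_hi: float = 18.0
    numtaps: int = 1001
    weights: tuple[float, float, float] = (0.01, 1.0, 10.0)

    def __post_init__(self) -> None:
        if not (0 < self.pass_lo < self.pass_hi < self.fs / 2):
            raise ValidationError("need 0 < pass_lo < pass_hi < fs/2")
        if not (0 <= self.stop_lo < self.pass_lo):
            raise FilterDesignError("lower stop edge must lie in [0, pass_lo)")
        if not (self.pass_hi < self.stop_hi < self.fs / 2):
            raise FilterDesignError("upper stop edge must lie in (pass_hi, fs/2)")
        if self.numtaps % 2 == 0 or self.numtaps < 3:
            raise ValidationError("numtaps must be odd and >= 3 (type-I linear phase)")


@dataclasses.dataclass
class DenoiseSpec:
    """Multilevel wavelet soft-threshold denoising parameters.

    Per-level universal thresholds lambda_d = sigma_d * sqrt(2 ln n), with
    sigma_d the robust MAD estimate median(|d|)/0.6745 of that level's
    detail coefficients; approximation coefficients are left untouched.
    """

    wavelet_name: str = "sym8"
    levels: int | None = None  # None -> min(5, floor(log2 n) - 2)
    threshold_rule: str = "universal-per-level"
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.threshold_rule != "universal-per-level":
            raise ValidationError("threshold_rule must be 'universal-per-level'")
        if self.threshold_mode != "soft":
            raise ValidationError("threshold_mode must be 'soft'")
        if self.levels is not None and self.levels < 1:
            raise ValidationError("levels must be >= 1")


def denoise_wavelet(x: np.ndarray, spec: DenoiseSpec | None = None) -> np.ndarray:
    """Adaptive per-level soft-threshold wavelet denoising.

    Decomposes ``x`` into ``levels`` detail bands, soft-thresholds each band
    at its own universal threshold, and reconstructs.  Output length equals
    input length.
    """
    spec = spec or DenoiseSpec()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("signal too short to denoise")
    max_levels = int(np.floor(np.log2(n)))
    levels = spec.levels if spec.levels is not None else max(1, min(5, max_levels - 2))
    if levels > max_levels:
        raise ValidationError(
            f"levels={levels} too deep for n={n}; at most {max_levels} feasible"
        )
    coeffs = pywt.wavedec(x, spec.wavelet_name, level=levels)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        sigma = np.median(np.abs(d)) / 0.6745
        lam = sigma * np.sqrt(2.0 * np.log(n))
        out.append(pywt.threshold(d, lam, mode="soft") if lam > 0 else d)
    return pywt.waverec(out, spec.wavelet_name)[:n]


def design_remez_bandpass(spec: FilterSpec | None = None) -> np.ndarray:
    """Design the equiripple linear-phase FIR bandpass (Parks-McClellan).

    Returns ``numtaps`` symmetric coefficients (h[k] == h[numtaps-1-k]).
    """
    spec = spec or FilterSpec()
    bands = [0.0, spec.stop_lo, spec.pass_lo, spec.pass_hi, spec.stop_hi, spec.fs / 2]
    h = _signal.remez(
        spec.numtaps, bands, [0.0, 1.0, 0.0], weight=list(spec.weights), fs=spec.fs
    )
    # Enforce exact symmetry (remez is symmetric up to rounding).
    return 0.5 * (h + h[::-1])


def frequency_response(h: np.ndarray, freqs_hz, fs: float) -> np.ndarray:
    """|H(f)| evaluated by a direct discrete-time Fourier sum."""
    h = np.asarray(h, dtype=float)
    k = np.arange(h.size)
    w = 2.0 * np.pi * np.atleast_1d(np.asarray(freqs_hz, dtype=float)) / fs
    return np.abs(np.exp(-1j * np.outer(w, k)) @ h)


def apply_filter(x: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Zero-phase filtering via group-delay-compensated convolution.

    The kernel is symmetric (linear phase), so a 'same'-mode convolution on
    a reflect-padded signal is exactly zero-phase.  Output length equals
    input length.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(coefficients, dtype=float)
    if x.size <= h.size:
        raise ValidationError(
            f"signal length {x.size} must exceed filter length {h.size}"
        )
    half = h.size // 2
    xp = np.pad(x, half, mode="reflect")
    return _signal.fftconvolve(xp, h, mode="same")[half:half + x.size]


def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]: (x - min) / (max - min)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSegmentError("degenerate segment: max == min")
    return (x - lo) / (hi - lo)


def skewness_sqi(x: np.ndarray) -> float:
    """Sample skewness m3 / m2^{3/2} (biased central moments).

    Used as a signal-quality index: a segment passes iff the value is > 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 samples for skewness")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0:
        raise ValidationError("constant input has undefined skewness")
    return float(np.mean(xc**3) / m2**1.5)


def segment_recording(
    x: np.ndarray, fs: float, segment_seconds: float = 2.1, n_segments: int | None = None
) -> list[np.ndarray]:
    """Cut a recording into consecutive non-overlapping fixed-length windows.

    Each window has exactly ``round(segment_seconds * fs)`` samples; the
    trailing remainder is discarded.  ``n_segments=None`` takes as many full
    windows as fit.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(segment_seconds * fs))
    if win < 1:
        raise ValidationError("segment window must span at least 1 sample")
    if n_segments is None:
        n_segments = x.size // win
    need = n_segments * win
    if x.size < need:
        raise ValidationError(
            f"recording of {x.size} samples too short: {n_segments} segments "
            f"of {win} samples need {need}"
        )
    return [x[i * win:(i + 1) * win].copy() for i in range(n_segments)]


def preprocess_segment(
    x: np.ndarray,
    denoise_spec: DenoiseSpec | None = None,
    filter_spec: FilterSpec | None = None,
    coefficients: np.ndarray | None = None,
) -> np.ndarray:
    """Full conditioning chain: denoise -> zero-phase bandpass -> min-max.

    ``coefficients`` may carry a pre-designed kernel so batch callers pay
    the Remez design once.
    """
    if coefficients is None:
        coefficients = design_remez_bandpass(filter_spec)
    y = denoise_wavelet(x, denoise_spec)
    y = apply_filter(y, coefficients)
    return normalize_minmax(y)
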