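"""Continuous wavelet transform scalograms with the analytic Morlet wavelet.

The CWT of a signal x(t) at scale a and shift b is the inner product of x
with a scaled, shifted copy of the mother wavelet; here the mother wavelet
is the analytic Morlet (Gabor) wavelet

    psi(t) = pi^{-1/4} exp(j omega0 t) exp(-t^2 / 2),

whose center frequency omega0 links scale to analysis frequency via
a = omega0 / (2 pi f).  Frequencies are laid on a log grid with a fixed
number of voices per octave, and the magnitude |CWT(a, b)| over the
(frequency, time) grid is the scalogram.

Normalization: rows are scaled by 1/a by default ("l1"), which makes the
response to a pure tone peak exactly at the tone's frequency and agree in
amplitude across scales (the convention of MATLAB's cwt filter bank, which
this stage mirrors).  The energy convention 1/sqrt(a) ("l2") is available;
it carries a small (~omega0^{-2}) systematic scale bias for tones.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.signal import fftconvolve

from .errors import ValidationError


@dataclasses.dataclass
class CWTConfig:
    """Analysis grid and wavelet parameters for the Morlet CWT."""

    omega0: float = 6.0
    voices_per_octave: int = 12
    freq_min: float = 0.1
    freq_max: float = 50.0
    fs: float = 1000.0
    normalization: str = "l1"  # "l1" (tone-amplitude) or "l2" (energy)
    envelope_support: float = 5.0  # kernel truncated at |t/a| <= this

    def __post_init__(self) -> None:
        if not (0 < self.freq_min < self.freq_max <= self.fs / 2):
            raise ValidationError("need 0 < freq_min < freq_max <= fs/2")
        if self.voices_per_octave < 1:
            raise ValidationError("voices_per_octave must be >= 1")
        if self.omega0 <= 0:
            raise ValidationError("omega0 must be > 0")
        if self.normalization not in ("l1", "l2"):
            raise ValidationError("normalization must be 'l1' or 'l2'")

    def frequencies(self) -> np.ndarray:
        """Descending log-spaced analysis frequencies (Hz).

        ``voices_per_octave`` frequencies per factor-of-two, from freq_max
        down to the last grid point >= freq_min.
        """
        n_octaves = np.log2(self.freq_max / self.freq_min)
        k = np.arange(int(np.floor(n_octaves * self.voices_per_octave)) + 1)
        freqs = self.freq_max * 2.0 ** (-k / self.voices_per_octave)
        if freqs.size == 0:
            raise ValidationError("empty frequency grid")
        return freqs


@dataclasses.dataclass
class Scalogram:
    """|CWT| magnitude over a descending-frequency x time grid."""

    magnitude: np.ndarray  # n_freq x n_time, nonnegative
    freqs_hz: np.ndarray  # descending
    times_s: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=float)
        if m.ndim != 2:
            raise ValidationError("magnitude must be 2-D")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValidationError("magnitudes must be finite and >= 0")
        if m.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValidationError("axis lengths must match matrix dimensions")
        self.magnitude = m


def morlet_kernel(scale: float, fs: float, omega0: float, support: float = 5.0) -> np.ndarray:
    """Sampled analytic Morlet wavelet at one scale (unit L2 energy in
    continuous time), truncated where the Gaussian envelope is negligible."""
    half = int(np.ceil(support * scale * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / scale
    return np.pi**-0.25 * np.exp(1j * omega0 * u) * np.exp(-0.5 * u**2)


class MorletFilterBank:
    """Precomputed per-frequency Morlet kernels for repeated transforms.

    Building the bank once and calling :meth:`transform` on many segments
    avoids re-sampling the (long, low-frequency) kernels per segment.
    """

    def __init__(self, cfg: CWTConfig):
        self.cfg = cfg
        self.freqs = cfg.frequencies()
        self.scales = cfg.omega0 / (2.0 * np.pi * self.freqs)
        dt = 1.0 / cfg.fs
        self.kernels = []
        for a in self.scales:
            k = morlet_kernel(a, cfg.fs, cfg.omega0, cfg.envelope_support)
            norm = dt / a if cfg.normalization == "l1" else dt / np.sqrt(a)
            # psi is conjugate-symmetric under time reversal, so convolution
            # with psi itself realizes correlation with psi*.
            self.kernels.append(k * norm)

    def transform(self, x: np.ndarray) -> Scalogram:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size < 16:
            raise ValidationError("signal must be 1-D with length >= 16")
        rows = np.empty((len(self.kernels), x.size))
        for i, k in enumerate(self.kernels):
            rows[i] = np.abs(fftconvolve(x, k, mode="same"))
        times = np.arange(x.size) / self.cfg.fs
        return Scalogram(rows, self.freqs.copy(), times)


def cwt_morlet(x: np.ndarray, cfg: CWTConfig | None = None) -> Scalogram:
    """Analytic-Morlet CWT magnitude of ``x`` on the configured log grid.

    Edges are zero-padded (implicitly, by 'same' convolution); no
    cone-of-influence masking is applied, so images are reproducible
    functions of the raw samples.
    """
    return MorletFilterBank(cfg or CWTConfig()).transform(x)


def render_scalogram(
    s: Scalogram, out_size: tuple[int, int] = (224, 224), cmap: str = "viridis"
) -> np.ndarray:
    """Render a scalogram to a fixed-size 8-bit RGB image.

    Per-image min-max scaling of the linear magnitude to [0, 1],
    area-averaging (box) resize to ``out_size`` (H, W), then a fixed
    perceptually ordered colormap.  Box resampling is deliberate: when
    thousands of time columns collapse into tens of pixels, point-sampled
    interpolation aliases short dicrotic-notch bursts and makes pixel
    patterns depend on beat phase, while area averaging preserves band
    energy.  A constant magnitude matrix renders as the colormap's floor
    color.  Deterministic: identical scalograms give identical bytes.
    """
    H, W = out_size
    if H < 1 or W < 1:
        raise ValidationError("output size must be positive")
    m = s.magnitude
    lo, hi = m.min(), m.max()
    norm = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    resized = np.asarray(
        Image.fromarray(norm.astype(np.float32), mode="F").resize((W, H), Image.BOX)
    )
    rgba = colormaps[cmap](np.clip(resized, 0.0, 1.0))
    return (rgba[..., :3] * 255.0).round().astype(np.uint8)


def dominant_frequency(s: Scalogram, central_fraction: float = 0.5) -> float:
    """Frequency (Hz) with the largest time-averaged magnitude.

    Averaging is restricted to a central time window to keep zero-padding
    edge decay from biasing the estimate.
    """
    n = s.magnitude.shape[1]
    k = max(1, int(round(n * central_fraction)))
    start = (n - k) // 2
    profile = s.magnitude[:, start:start + k].mean(axis=1)
    return float(s.freqs_hz[int(np.argmax(profile))])
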