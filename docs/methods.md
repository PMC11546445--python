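# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `ppgnet`. It is the package's own account of its science;
every empirical statement here is something the test suite or
`scripts/acceptance.py` computes.

## Problem setting

Single-channel photoplethysmography (PPG) measures microvascular
blood-volume changes optically. The pipeline classifies short PPG segments
into four blood-pressure stages — Normal (N), Prehypertension (P), Stage 1
(S1) and Stage 2 (S2) hypertension — via a three-step chain: signal
conditioning, time-frequency imaging, and a convolutional classifier. The
emulated acquisition design is: per subject, three 2.1-s segments sampled
at 1000 Hz, each kept only if its sample skewness exceeds zero (the
skewness signal-quality index, SQI), with the reference cohort comprising
657 segments from 219 subjects in class mix 240/255/102/60 (N/P/S1/S2
segments, i.e. 80/85/34/20 subjects).

## Synthetic cohort generator

`ppgnet.synth` generates seeded cohorts so the entire chain is testable
without recordings. Each beat is a two-Gaussian waveform — a systolic peak
of width `systolic_width` plus a dicrotic bump delayed by
`reflection_delay`, scaled by `notch_amplitude`, with width 0.6× systolic —
laid down quasi-periodically with per-beat period jitter (uniform ±3%) and
per-beat amplitude jitter (±5%), plus sinusoidal baseline wander
(default amplitude 0.05 at 0.25 Hz) and white noise (default sd 0.02,
relative to unit systolic amplitude). Segments are regenerated (new beat
phase; up to 100 retries) until they pass the skewness gate, mirroring the
acquisition saving rule; in practice the positive-pulse waveform passes on
the first draw almost always.

Per-class default morphologies form a monotone gradient from N to S2:
heart-rate ranges (62–68, 69–75, 77–83, 85–91 bpm, i.e. centers
65/72/80/88, pairwise disjoint), decreasing notch amplitude
(0.50/0.35/0.20/0.10), narrowing systolic width
(55/48/42/37 ms) and shortening reflection delay (300/280/260/240 ms).
These are **fixtures**: they give the classifier a learnable,
physiologically flavored signal and are not claims about hypertension
physiology. What passing tests show is that the pipeline can learn
class-dependent pulse morphology under subject-aware evaluation; they say
nothing about real hemodynamics, sensor artifacts, skin-tone or motion
effects, which the generator does not model.

A note on separability: with ±3% per-beat period jitter, the 1–2 bpm gaps
between adjacent heart-rate ranges can transiently close, so a boundary
subject's rate cue may overlap the neighboring class; the stepwise cues
(notch amplitude, width, delay) remain disjoint. Held-out accuracy on
40-subject cohorts is therefore high but not structurally 100%.

## Signal conditioning

Order: denoise → bandpass → normalize. Each step preserves length; the
output lies in [0, 1].

* **Adaptive wavelet denoising** (`denoise_wavelet`): multilevel `sym8`
  decomposition (default levels = min(5, ⌊log2 n⌋ − 2)); each detail band
  `d` is soft-thresholded at its own universal threshold
  λ_d = σ_d √(2 ln n), σ_d = median(|d|)/0.6745; approximation
  coefficients untouched. Per-level thresholds adapt to non-stationary,
  scale-dependent noise. Caveat: when genuine signal leaks into the
  deepest detail band (slow tones at deep level counts), the MAD estimate
  inflates and the band is over-thresholded — transparency on clean
  signals holds when the signal content sits inside the approximation
  band.
* **Equiripple FIR bandpass** (`design_remez_bandpass`): Parks–McClellan
  design, passband 0.05–16 Hz, stopbands below 0.01 Hz and above 18 Hz,
  1001 taps at fs = 1000 Hz, error weights (0.01, 1, 10). The sub-0.05 Hz
  transition is not realizable at this length (it would need ~10⁵ taps);
  the small lower-stop weight concentrates the equiripple error budget on
  the passband (|H(8 Hz)| ≈ 1.00) and the upper stopband
  (|H(100 Hz)| ≈ 0.003). DC gain is ≈ 0.97, immaterial because min-max
  normalization follows; on 2.1-s segments the filter's effective action
  is the 16 Hz lowpass.
* **Zero-phase application** (`apply_filter`): the symmetric kernel is
  applied by 'same'-mode convolution on a reflect-padded signal —
  exactly zero phase for a linear-phase FIR, so pulse landmarks stay
  aligned for the scalogram.
* **Min-max normalization**: (x − min)/(max − min); constant segments
  raise a degenerate-segment error for the caller to drop.
* **Skewness SQI**: biased sample skewness m₃/m₂^{3/2} (no small-sample
  correction — only the sign is used by the gate).

## Morlet scalograms

The continuous wavelet transform at scale a and shift b correlates the
signal with scaled/shifted copies of the analytic Morlet (Gabor) wavelet
ψ(t) = π^{-1/4} e^{jω₀t} e^{-t²/2}, with ω₀ = 6 (the standard
admissibility choice). Analysis frequencies sit on a log grid
(12 voices/octave, 0.1–50 Hz by default) with a = ω₀/(2πf); kernels are
truncated at |t/a| = 5 (envelope < 4·10⁻⁶) and applied by FFT
convolution with implicit zero padding and no cone-of-influence masking,
so images are reproducible functions of the samples.

**Normalization.** Rows are scaled 1/a ("l1") by default, which makes a
pure tone's response peak exactly at the tone's frequency and agree in
amplitude across scales — the convention of MATLAB-style CWT filter
banks. The energy convention 1/√a ("l2") is available; it carries a small
systematic scale bias for tones (the response √a·e^{-(aω-ω₀)²/2} peaks at
aω = (ω₀+√(ω₀²+2))/2, ≈ 0.02 octave for ω₀ = 6), which at 12 voices/octave
can move a tone's argmax off the nearest grid frequency. Frequency
localization is verified against direct numerical integration of the CWT
inner product.

**Rendering** (`render_scalogram`): linear magnitude, per-image min-max
to [0, 1], area-averaging (box) resize to the target size, then a fixed
perceptually ordered colormap (viridis) to 8-bit RGB, saved as PNG
(lossless). Area averaging rather than bilinear subsampling matters: a
2100-column scalogram squeezed to 64 columns undersamples the ~30 ms
dicrotic-notch bursts, and point-sampling makes pixel patterns depend on
beat phase; averaging preserves band energy and removes that nuisance.
Whether to render linear or log magnitude was an open choice; linear is
the default and the colormap/size are config.

## Balancing and evaluation protocol

* **SMOTE** operates on equal-length *signal vectors* before scalogram
  rendering: x_new = x + λ(x_nn − x), λ ~ U[0,1], x_nn one of the k = 5
  Euclidean nearest same-class neighbors. Interpolating signals yields
  valid pulse trains whose scalograms are recomputed; interpolating
  rendered pixels would not. Every synthetic vector inherits its parent's
  `source_subject_id`.
* **Undersampling** reduces over-represented classes to the target
  (default 250) by uniform subset without replacement.
* **Subject-aware split**: subjects (grouped by source id, so synthetic
  derivatives travel with their parent) are shuffled and
  round(0.2·n) held out; the 5-fold plan partitions training subjects
  into folds differing in size by ≤ 1. Balancing defaults to the training
  side only, after the split (no synthetic leakage); a dataset-wide
  "dataset_wide" mode reproduces the reference bookkeeping
  (240/255/102/60 → 250 each).
* All split/balance operations are pure functions of (inputs, seed).

## PPG-NET

An Xception-style graph of depthwise-separable convolutions: a
depthwise Dk×Dk per-channel convolution (Dk²M parameters) followed by a
1×1 pointwise mix (MN parameters) replaces a standard convolution's Dk²MN.
Three flows: entry (two standard 3×3 stem convolutions, the first with
stride 2, then downsampling residual blocks — two separable convolutions,
2×2 max pooling, strided 1×1 convolution shortcut), middle
(identity-shortcut residual blocks of three separable convolutions), exit
(separable convolutions → global average pooling → dense softmax over 4
classes). Batch normalization after every convolution (switchable);
convolutions carry no bias (normalization absorbs offsets, and parameter
counts then match the Dk²M + MN arithmetic exactly); the dense head has a
bias. Weights are He-initialized from the seeded generator — the full
network, including backpropagation and SGD, is implemented in numpy
(float32), so runs are deterministic given the seed.

The default graph (stem 32/64, entry 128/256/728, 4 middle blocks, exit
1024 on 224×224 inputs) mirrors the full-scale design; the **desk-scale**
configuration used for CPU experiments is stem 8/16, entry 32/64, one
middle block, exit 128 on 64×64 inputs (~37k core parameters). Exact
layer widths of the reference network are not fully legible from its
description, so all widths are configuration.

**Training protocol** (defaults mirror the reference setup): SGD,
learning rate 0.01, batch size 12, up to 100 epochs, 5 folds,
cross-entropy loss. Momentum 0.9 (standard practice for this family of
networks; not stated in the reference protocol, switchable). Shuffling
happens only within the training side. Early stopping monitors validation
accuracy with patience 10; on a new maximum the weight snapshot and
patience reset, on a tie the snapshot refreshes (the latest best epoch has
had the most training) but patience still counts down, so a flat plateau
stops training; the restored weights never postdate the best validation
epoch. Ties at prediction argmax resolve to the lowest class index.
ImageNet weight transfer is not emulated — initialization is random.

Evaluation supports both protocols the reference design describes:
subject-aware 5-fold cross-validation on the training side (per-fold
best-validation accuracy, and an ensemble that averages the fold models'
probabilities) and a single held-out test evaluation.

## Metrics

Per class, the 4×4 confusion matrix is marginalized one-vs-rest to
TP/FP/FN/TN, giving Acc, Pre, Sen, Spe and F1; per-class accuracy is the
one-vs-rest accuracy (the only reading under which per-class and overall
accuracy can differ). Overall accuracy is the trace ratio, which equals
the support-weighted mean of per-class sensitivities. 0/0 denominators
yield 0 and the (class, metric) pair is flagged in the report. The
implementation is verified against a brute-force counting oracle on random
label vectors.

## Problem sizes for CPU runs

The default pipeline configuration runs a 40-subject balanced cohort
(120 segments), 64×64 images over a 0.5–16 Hz analysis band, the
desk-scale network, and 20 training epochs — sizes chosen so a complete
end-to-end run takes minutes on one CPU while still exercising every
stage. The full-scale defaults (219 subjects, 224×224 images, the large
graph, 100 epochs) are available through configuration.

## Known limitations

* The generator does not model motion artifacts, sensor coupling, skin
  tone, arrhythmias, or genuine blood-pressure physiology; results on it
  bound nothing about clinical data.
* With per-beat period jitter, adjacent-class heart-rate gaps can close
  for boundary subjects; desk-scale held-out accuracy is typically
  ≥ 95% but single-subject errors (~4% of the test set each) occur for
  some cohort seeds.
* The FIR lower band edge is nominal at realizable tap counts (above).
* Wavelet-denoising transparency degrades when signal energy reaches the
  deepest detail level (above).
* The numpy network is CPU-bound and practical up to roughly desk scale;
  it is not a deployment artifact.
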