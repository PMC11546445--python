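# ppgnet

Blood-pressure stage classification from photoplethysmography (PPG)
scalograms: a complete, seeded, CPU-friendly pipeline for researchers who
want to study — or stress-test — the popular "PPG → CWT image → CNN"
recipe for non-invasive hypertension monitoring.

A single-channel PPG segment x(t) is conditioned (adaptive wavelet
denoising, equiripple FIR bandpass 0.05–16 Hz, 0–1 min-max normalization),
transformed with the continuous wavelet transform

    CWT(a, b) = (1/a) ∫ x(t) ψ*((t − b)/a) dt,
    ψ(t) = π^(-1/4) · exp(jω₀t) · exp(−t²/2)   (analytic Morlet, ω₀ = 6),

rendered as a |CWT(a, b)| scalogram image on a log-frequency grid, and
classified into the four stages N / P / S1 / S2 by **PPG-NET**, an
Xception-style residual network of depthwise-separable convolutions
(Dk²M + MN parameters per layer instead of Dk²MN). Class imbalance is
handled by SMOTE in signal space plus majority undersampling, and all
evaluation is *subject-aware*: no subject — nor any synthetic record
interpolated from that subject — ever appears on both sides of a
train/test boundary or fold. A seeded synthetic cohort generator emulates
the acquisition design (three 2.1-s segments per subject at 1000 Hz,
skewness-SQI gating, the 240/255/102/60 class mix), so every stage is
testable offline.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Run the default desk-scale experiment (40-subject synthetic cohort,
64×64 scalograms, reduced PPG-NET, 5-fold subject-aware CV, held-out
test):

```python
from ppgnet.pipeline import run_pipeline

result = run_pipeline({"seed": 0}, out_dir="runs/demo")
print(result.report.format_table())
```

which prints (exact numbers for seed 0):

```
Class        Acc     Pre     Sen     Spe      F1
N          1.000   1.000   1.000   1.000   1.000
P          0.958   0.750   1.000   0.952   0.857
S1         0.958   1.000   0.889   1.000   0.941
S2         1.000   1.000   1.000   1.000   1.000
Overall    0.958
```

Reading: 24 held-out segments from 8 unseen subjects; per-class rows are
one-vs-rest tallies (e.g. one S1 segment of a boundary-heart-rate subject
was predicted P, costing S1 sensitivity and P precision); `Overall` is
plain accuracy. Artifacts written under `runs/demo/`: the cohort manifest
and signals, scalogram PNGs, the split plan JSON, per-fold weights, and
the metrics report (JSON + text).

The same run from the shell:

```bash
ppgnet pipeline --out runs/demo          # default config
ppgnet synth --out runs/cohort --subjects 40 --seed 0   # stages also run alone
ppgnet split --manifest runs/cohort/manifest.csv --out plan.json
```

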