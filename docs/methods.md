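# Methods

## The signal chain

The Analgesia Nociception Index (ANI) estimates parasympathetic (vagal)
tone from the respiratory sinus arrhythmia of the RR-interval series. The
pipeline assumes a single-lead ECG or a beat-annotated tachogram, a roughly
stationary respiratory rate inside each 64-s window, and that artifact
beats (ectopy, missed detections) are sparse enough for local statistics to
identify them.

**R-peak detection.** A Pan–Tompkins-style chain: 5–30 Hz band-pass,
derivative energy, 150-ms moving integration, adaptive threshold at 20% of
the maximum, 250-ms refractory period, and refinement of each candidate to
the local ECG maximum. This detector is validated only against the
package's own synthetic ECG (ground-truth beat times); it makes no claim of
clinical-grade QRS detection.

**Artifact filter.** Auto-adaptive thresholds in a 5-sample moving window.
Head samples (indices 0–4) outside mean ± 2 SD of the whole series are
replaced by the whole-series mean. Body samples (5 … n−2) are replaced by
the mean of their previous five samples when (1) the sample falls below the
moving mean − 2 SD while its successor exceeds the moving mean + 2 SD, or
(2) the sample or its successor falls below 0.75× the predecessor, or
(3) the sample exceeds 1.25× the predecessor. The last sample uses the
0.75×/1.25× bounds alone. Three documented choices where the procedure is
underdetermined: replacements are applied sequentially in place (so one
artifact cannot cascade through subsequent moving statistics), the
successor value is always read from the original series (it has not been
visited yet), and SDs are population SDs (threshold use, not inference).
A sample flagged only through its successor (rule 2, second clause) flags
the current index, not the successor; the replacement then equals the
sample's own window mean, so a clean predecessor is not distorted.

**Resampling and windowing.** The filtered tachogram is linearly
interpolated onto an 8-Hz grid spanning the beat-time range (no
extrapolation), then cut into 512-sample (64-s) windows advancing 8 samples
(1 s). Each window is mean-centered and divided by its L2 norm, so window
amplitudes are in normalized units and the index is scale-free.

**Wavelet band-pass.** The normalized window is decomposed with the 4-tap
Daubechies wavelet (`db2` in PyWavelets naming — four filter coefficients,
the classic D4) using periodized boundary handling, and reconstructed from
detail levels {4, 5} only: at 8 Hz these span the dyadic bands 0.25–0.5 and
0.125–0.25 Hz, the closest dyadic cover of the stated 0.15–0.5 Hz HF band.
A paper-literal `levels=(3, 4, 5)` configuration (additionally 0.5–1.0 Hz)
is exposed but not the default: the published description does not state
the sampling rate the transform is taken at, and at 1 Hz a 64-sample window
cannot support levels 3–5 covering that band at all. Band selectivity on
pure tones: ≥ 80% energy retained at 0.25 Hz, ≤ 20% at 0.05 Hz (measured:
~94% / ~4%).

**Envelope and areas.** The RRHF is decimated to the 1-Hz analysis grid
(`analysis_rate_hz`, configurable to 8 Hz; differences are small
interpolation effects). Local extrema use strict neighbor comparison with
plateau-midpoint selection — a deterministic tie-break. The upper
(lower) envelope interpolates linearly through the maxima (minima) and is
held constant beyond the first/last extremum. The envelope gap is
integrated by an exact trapezoid rule over four 16-s sub-windows of the
[0, 64) s span (the gap is held beyond the last grid point, so a constant
gap g yields exactly 16·g per sub-window and at most 0.2 × 64 = 12.8 s in
total). Windows with fewer than two maxima or two minima are degenerate:
the envelope collapses to the global max/min constants. ANI is
100 × (5.1 × AUCmin + 1.2)/12.8 clipped to [0, 100] (the raw affine form
exceeds 100 above AUCmin ≈ 2.27 s); degenerate windows still emit a value
from their (possibly zero) area but carry a nonzero quality flag, keeping
the per-second series gap-free for downstream windowing.

## Label harmonization

Raters are compared by one-way ANOVA with the **per-patient mean score per
rater** as the observational unit — per-second values are massively
autocorrelated and would inflate significance arbitrarily. While the ANOVA
is significant at α = 0.05 and more than two raters remain, the rater whose
group mean deviates most from the others is excluded, provided its Tukey
HSD pairwise comparisons are significant against the majority of the
remaining raters; the published study performed this identification
visually from an interval plot, so the formal rule here is a disciplined
stand-in. The consensus label is the per-second arithmetic mean of the
included raters.

## Regressors

Both models read standardized, non-overlapping 10-s windows of (100 − ANI);
the label is the consensus score at the window's final second, and
standardization statistics (mean, population SD) come from the training
patients only. Labels are divided by 100 to match the sigmoid output; the
loss is MAE on that scale, reported ×100 — the choice that makes training
losses commensurate with the reported MAEs, since the published account
never names the loss.

* MLP: 10 → 32 → 32 → 1; hidden layers are affine → batch normalization →
  sigmoid (the stated order lists normalization inside the hidden layer
  before the activation; it is otherwise unstated); Adam, lr 0.001,
  batch 32, 30 epochs.
* LSTM: two stacked layers of 32 standard cells (forget/input/output gates
  with sigmoid, candidate and cell output with tanh); "batch normalization
  applied to each LSTM layer" is implemented as normalization of each
  layer's output sequence jointly over batch and time (within-cell
  variants are nonstandard and unstated); sigmoid head on the last step;
  Adamax, lr 0.001, batch 32, 15 epochs.

Weights initialize uniformly with fan-in scaling from the run seed; batch
normalization uses batch statistics in training and exponential running
statistics (momentum 0.1) at inference, so a window's prediction does not
depend on its batch companions. No early stopping; per-epoch shuffling is
driven by the same seed, so training is bit-reproducible. The networks run
on a small reverse-mode autodiff core written on numpy (validated against
finite differences in the test suite); no deep-learning framework is
required.

## Evaluation

Splits are by patient (seeded-random rather than the study's manual
selection, for reproducibility): holdout train/validation/test, and
cross-validation that fixes one test set and rotates the remaining patients
through pairwise-disjoint validation sets covering each patient exactly
once. Errors are MAE per test patient, aggregated as mean ± **sample** SD
(n − 1) — the convention that reproduces the published overall rows exactly
from their printed per-patient and per-fold values. The best fold/model is
the argmin of overall MAE; prediction-curve shape is left to human judgment
via the persisted per-patient prediction arrays.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, per
patient and fully deterministic given the config seed (per-patient
`SeedSequence` children):

* **Latent pain** (1 Hz, 0–100): baseline drawn from 15–25, an initial
  exponential-decay spike (amplitude 60, time constant 60 s — the
  induction/intubation analog), and smooth logistic plateau events
  (amplitude 15–40, half-width 20–45 s, 8-s shoulders) jittered within
  equal slots so events never merge.
* **RR point process**: instantaneous RR(t) = 800 ms − 1.0·pain(t)
  + A(t)·sin(2π·0.25·t + φ) + drift + white noise (3 ms SD), integrated
  first-order (next beat RR(t)/1000 s after the current one), with
  respiratory amplitude A(t) = 40 ms · (1 − pain/100). The drift is a
  single constant-envelope 0.03–0.06 Hz tone of 25 ms amplitude (Mayer-wave
  analog). Because the window normalization makes ANI scale-free, the index
  measures the HF *share* of window variance; the drift is the stable
  competitor in the norm that converts RSA suppression into ANI contrast. A
  single tone is used deliberately: its 64-s windowed power is nearly
  constant, whereas a random narrowband mixture fluctuates window-to-window
  and would superimpose ANI noise unrelated to pain. Its band sits well
  below the 0.125-Hz edge of the HF wavelet band to keep leakage small.
* **Artifacts** (per-interval probability 0.005): ectopic events replace
  one interval RR by (0.4·RR, 1.6·RR) — premature beat plus compensatory
  pause — and missed-beat events merge two adjacent intervals; injected
  positions are recorded for filter validation.
* **Raters**: five curves equal to pain + bias + AR(1) noise
  (ρ = 0.99 at 1 Hz, stationary SD 3 — hand-drawn score curves wander
  slowly rather than jitter), clipped to [0, 100]; default biases
  (0, 0, 0, −10, 0) reproduce one strongly low-biased rater.
* **ECG** (optional): one biphasic QRS-like template per beat at 512 Hz
  with optional wander/noise; ground-truth beat times are kept for detector
  tests.

What the generator does **not** model: pharmacokinetics, P/T-wave
morphology, respiratory-rate variation, nonstationary noise, or any
quantitative pain→HRV transfer function taken from data — the linear
couplings are modeling choices. Passing the end-to-end tests therefore
shows the pipeline's internal consistency (the models recover labels that
are functions of the features; the index tracks the latent signal the
generator encodes), not clinical performance on real cohorts.

## Problem sizes and tolerances

Test and acceptance runs use cohorts of 8–10 patients × 900 s (the package's
default synthetic scale; the noiseless recovery experiment yields ~660
training windows). Unit-norm checks use 1e−9; envelope/AUC sinusoid checks
allow 10% (envelope sampling and wavelet passband ripple); wavelet
selectivity bounds are 80%/20%; the biased-rater exclusion check demands
≥ 95% over 20 cohorts. Published aggregation rows are reproduced to the
printed precision (±0.001; one LSTM row differs by 0.0006 because the
original aggregated unrounded per-patient values).

## Known limitations

* The published "wavelet components 3 to 5" cannot be reconciled with both
  the 0.15–0.5 Hz band and a 1-Hz/64-sample window under dyadic band
  arithmetic; both readings are exposed via `AniConfig.levels` and neither
  is asserted as the original intent.
* Vendor-device (MDoloris) bit-compatibility is out of scope; the device's
  exact implementation is not fully published.
* The regressors' absolute MAEs on real cohorts are not reproducible here:
  the original loss, initialization, and shuffling are unstated, and the
  clinical data are available only on request.
* No streaming/real-time operation; the pipeline is batch-oriented.
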