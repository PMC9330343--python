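# anihrv

Intraoperative nociception monitoring from heart-rate variability: compute
the **Analgesia Nociception Index (ANI)** from RR-interval series, harmonize
multi-rater **Expert Assessment of Pain Score (EAPS)** curves, and train
compact **MLP / LSTM regressors** that predict EAPS from 10-s windows of
(100 − ANI), evaluated patient-wise with holdout and cross-validation.

The package is aimed at researchers studying HRV-based pain monitoring who
need a transparent, tested reference implementation of the ANI signal chain
and of the downstream pain-score regression — plus a synthetic cohort
generator, so every stage is exercisable without access to clinical
recordings.

## The index

Respiratory sinus arrhythmia — the 0.15–0.5 Hz vagally mediated modulation of
the beat-to-beat (RR) interval — shrinks when nociception drives sympathetic
activation. ANI quantifies it per 64-s window of the artifact-filtered,
8-Hz-resampled RR series (512 samples, advancing 1 s):

1. mean-center the window and divide by its L2 norm
   (`S = √Σ(RRᵢ − M)²`), giving amplitudes in normalized units (n.u.);
2. band-pass to the HF band with a 4-tap Daubechies discrete wavelet
   transform (detail levels whose dyadic bands cover 0.15–0.5 Hz), yielding
   the high-frequency series RRHF;
3. connect local maxima (upper) and minima (lower) of RRHF with
   piecewise-linear envelope lines, split the window into four 16-s
   sub-windows, and integrate the envelope gap in each;
4. with AUCmin the smallest of the four areas (in seconds):

   **ANI = 100 × (5.1 × AUCmin + 1.2) / 12.8**, clipped to [0, 100],

   where 12.8 s = 0.2 n.u. × 64 s is the maximum possible whole-window area.

High ANI ⇒ strong respiratory modulation ⇒ low nociception; the model input
feature is its opposite, 100 − ANI, which moves with pain. Labels come from
five clinicians' per-second EAPS curves: a one-way ANOVA across raters
(observations: per-patient mean score) excludes systematically deviating
raters (Tukey HSD post hoc), and the remaining raters are averaged.

Both regressors read standardized, non-overlapping 10-s windows of
(100 − ANI) and predict the EAPS at the window's last second: an MLP
(10 → 32 → 32 → 1, batch normalization + sigmoid in each hidden layer, Adam,
30 epochs) and a two-layer stacked LSTM (32 units per layer, Adamax,
15 epochs), both with a sigmoid output trained on labels/100 under an MAE
loss. Errors are reported per test patient and aggregated as mean ± sample SD.

## Worked example

```python
import numpy as np
from anihrv import (SynthConfig, gen_cohort, compute_ani_series,
                    select_raters, consensus_label, ani_from_aucmin)

# closed-form points of the index
print(ani_from_aucmin(0.0), ani_from_aucmin(1.0))   # 9.375 49.21875

# a small synthetic cohort: latent pain drives RSA suppression
cohort = gen_cohort(SynthConfig(n_patients=3, duration_s=600, seed=1))
p = cohort.patients[0]
s = compute_ani_series(p.rr)                         # one value per second
print(len(s), round(s.ani.min(), 1), round(s.ani.max(), 1))
# 537 35.6 75.6   (time stamps start at the first full 64-s window)

# rater harmonization: the default cohort has one rater biased 10 points low
included = select_raters([q.raters for q in cohort])
print(included)                                      # ('A', 'B', 'C', 'E')
labels = consensus_label(p.raters, included)
print(round(float(labels.eaps.mean()), 1))           # 37.4
```

The ANI series tracks the latent pain inversely: windows over high-pain
segments show suppressed respiratory modulation, hence a small minimum
envelope area and a low ANI. On noiseless cohorts the rank correlation
between windowed latent pain and (100 − ANI) is ≈ 0.86.

The same pipeline is scriptable from the shell:

```bash
ani synth --n-patients 8 --duration 900 --seed 1 --outdir cohort/
ani preprocess --in cohort/rr_P001.csv --out rr_filtered.csv
ani compute --rr rr_filtered.csv --out ani.csv
ani consensus cohort/eaps_P*.csv --outdir consensus/
ani evaluate --n-patients 8 --duration 900 --seed 1 --out report.json
```

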