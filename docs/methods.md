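# Methods

`pediecg` classifies ~30-second single-lead smartwatch electrocardiograms
("iECGs") from children as healthy (normal sinus rhythm) or pathological.
The analysis has two parts: a CNN that labels the *morphology* of every
individual beat, and a rule-based decision tree that turns the beat labels,
the RR-interval series, and the patient's age into a record-level *rhythm*
diagnosis. This note documents the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the known
limits of what the test suite can show.

## Signal model and ingestion

Records are voltage time series in micro-volts sampled at 512 Hz, carried
by `IECGRecord` together with the patient's age (the decision tree is
age-aware, so age travels with the signal). The CSV dialect — optional
`key,value` header lines followed by one voltage per row — mirrors the
shape of a consumer health-app export; the exact header fields of such
exports are not standardized, so the reader accepts any header keys and
only interprets `sample-rate-hz`, `unit` (µV or mV, converted), `record-id`
and `age-years`. Write-then-read reproduces samples to 1e-6 µV (voltages
are written with six decimals).

## Synthetic iECG generation

Real pediatric iECG datasets are restricted, so every stage is developed
and tested against generated strips with exact ground truth. Beats are sums
of Gaussian lobes (P wave, QRS, T wave) with class-specific structure:

| class | morphology | QRS width at 10 % of peak |
|---|---|---|
| N | P wave, narrow QRS, upright T | 70 ms |
| R | widened QRS of two merged lobes (notch), discordant T | 110 ms |
| P | 2.5 ms pacing spike 55 ms before a wide QRS | 100 ms |
| V | wide QRS, no P wave, discordant T | 160 ms |
| W | short PR, delta-wave upstroke | 95 ms |
| S | narrow QRS with inverted P | 70 ms |

The R-peak of every template sits at the sample of maximum absolute
amplitude, which is what "ground-truth R-peak position" means downstream.
Strips place beats at RR = 60000/HR ms with multiplicative uniform jitter
(default fraction 0.05, i.e. RR coefficient of variation ≈ 0.03), then add
Gaussian broadband noise (default SD 20 µV), sinusoidal baseline wander
(default 50 µV at 0.3 Hz), and optionally a leading motion-artifact burst
(broadband, 8× QRS amplitude) covering the first seconds — artifacts
concentrate at the start of real pediatric recordings, especially in
neonates. The default QRS amplitude is 800 µV, a typical single-lead
pediatric R wave.

Cohorts draw ages uniformly over [0, 18) years and make exactly
round(n × pathology_fraction) records pathological, cycling through RBBB
runs, PVC-containing strips (15 % V beats), paced rhythm, bradycardia and
tachycardia. Healthy heart rates are drawn at least 8 bpm inside the
age-appropriate band and brady-/tachycardic rates at least 8 bpm outside
it, so generated truths are never borderline; the record-level truth label
is a pure function of the placed beat classes, the realized RR series and
the age band, recomputable from the ground-truth object alone.

What the generator does *not* emulate: atrial fibrillation, fusion and
aberrantly conducted beats, electrode pop/motion artifact inside the strip,
respiration-modulated RR variability, and the morphological diversity of
real pediatric pathology. Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent, not that its accuracy
transfers to clinical recordings.

## Segmentation

`trim_leading_artifact` removes the first 5 s when the 30–100 Hz power of
that window exceeds 4× the power of the remainder; a fixed 5 s window is
used because motion artifact at the start of a recording is a settling
phenomenon, and the decision is logged in record metadata. The detector is
an energy pipeline in the Pan–Tompkins tradition: band-pass (5–30 Hz,
order-2 Butterworth, zero-phase) → differentiate → square → 120 ms
moving-window integrate → adaptive threshold → refine each detection to
the local extremum of the filtered signal. Two deliberate choices:

* the threshold compares the *square root* of the integrated energy (an
  amplitude-scale envelope) against 30 % of a slowly varying local maximum
  envelope. In energy units, wide ventricular complexes carry ~20× less
  derivative energy than narrow beats and no single fraction separates all
  QRS morphologies from T waves; on the amplitude scale the measured
  separation is comfortable (QRS ≥ 0.36 of the envelope, T waves ≤ 0.23).
* the refractory period of the second pass adapts to 60 % of the median RR
  from a first pass, floored at 120 ms, so neonatal rates (RR ≈ 330 ms)
  stay detectable while T waves are rejected at slow adolescent rates.

All stages are sign-free or scale-relative, making detection invariant
under lead inversion and positive rescaling. Beat frames span RR-midpoint
to RR-midpoint (first/last beats mirror their single neighbor), so each
frame holds one full cardiac cycle at any rate and frame count always
equals peak count.

## Beat images and dataset construction

A frame renders as a square 8-bit grayscale image: black anti-aliased
1-pixel polyline on white, time mapped linearly to x, voltage min–max
normalized per beat with 5 % vertical padding (per-beat rather than
per-record normalization keeps every QRS at full scale regardless of
amplitude; it also makes rendering invariant to positive rescaling).
Constant frames render as a mid-height line. Sides default to 128 (linear
CNN) and 299 (three-flow CNN).

Dataset construction follows the training recipe: each image yields nine
two-thirds-size crops on a deterministic 3×3 anchor grid, bilinearly
rescaled to full size, for ten similar images per beat; pepper noise
("salt-and-pepper", here black-only) blackens exactly round(2 % × pixels)
distinct pixels; exactly round(70 % × n_train) training images are noised
(validation/test never); classes are balanced by downsampling to the
minimum class count (selection, never duplication); and the train/val/test
split (default 70/15/15) is stratified by class and, by default, grouped
by source record so beats of one child cannot leak across splits.

## Beat classifiers

Two CNN families sit behind one interface, implemented directly on numpy
(float32, im2col convolutions, explicit backpropagation, Adam):

* **linear** (128×128 input): three conv3×3 → ReLU → maxpool2 blocks with
  16/32/`last_conv_filters` filters, then flatten → dense
  (`last_dense_units`) → dropout → softmax. ~0.5 M parameters at defaults.
* **three_flow** (299×299 input): an entry flow (strided 3×3 convolution,
  then two residual blocks of depthwise-separable convolutions with
  strided 1×1 projection shortcuts), a middle flow of identity-residual
  separable blocks (default repeated 4×, configurable), and an exit flow
  (separable convolution → global average pooling → softmax).

Inputs are single-channel; pixels are inverted (1 − v/255) so the trace,
not the background, carries activation. Training minimizes cross-entropy
with mini-batch Adam, early-stops on validation loss and restores the
best-validation-epoch weights. Seeds fix initialization, shuffling and
dropout, so runs are reproducible. Defaults (learning rate 1e-3, dropout
0.25, batch 32, ≤12 epochs, patience 3) were chosen for stable single-CPU
convergence on the synthetic task; the hyperparameter search utility
trains each grid entry identically and ranks by final validation accuracy
(ties: lower validation loss, then grid order). The training problem sizes
used in the tests and the acceptance script (hundreds of images per class,
≤12 epochs) are the package's deliberate desk scale.

## Rhythm decision tree

Rules fire in fixed order, first match wins: (1) more than 30 % of beats
below confidence 0.5 → inconclusive; (2) ≥ 1 V beat → sinus with PVC;
(3) ≥ 60 % R beats → RBBB; (4) ≥ 60 % P beats → paced rhythm; (5) heart
rate (60000 / median RR; median for robustness to residual ectopy) outside
the age band → brady-/tachycardia; (6) RR coefficient of variation > 0.15
→ irregular rhythm; (7) else sinus rhythm. Only sinus rhythm binarizes to
healthy; only inconclusive binarizes to inconclusive. The evidence map
records every evaluated quantity and the single fired rule.

The default age bands (0–1 y: 90–180, 1–3 y: 80–160, 3–6 y: 75–140,
6–12 y: 65–130, 12–18 y: 55–120 bpm) are general pediatric reference
ranges shipped as editable YAML configuration; they are defaults of this
package, **not** thresholds published with any clinical study, whose
concrete decision-tree parameters are not public. Ordering PVC/morphology
rules before rate rules encodes that ectopy and conduction abnormalities
are diagnostic regardless of rate.

## Evaluation

Positive = pathology. An inconclusive prediction is treated as false on
both gold classes: predicted negative (fn) against pathological gold,
predicted positive (fp) against healthy gold — the one symmetric-penalty
reading consistent with 18 pathological / 30 healthy marginals in a
48-record table. With category-level predictions, naming the wrong
pathology also scores as predicted negative. Sensitivity and specificity
are reported as percentages rounded half-up to one decimal. McNemar's test
on paired correct/incorrect outcomes offers the exact form (two-sided
binomial tail of min(b, c) on b + c discordant pairs at ½) and the
continuity-corrected asymptotic chi-square; `auto` uses exact below 25
discordant pairs. b + c = 0 returns p = 1 with a degeneracy note.

## Known limitations and out-of-reach quantities

* The clinical dataset behind the published evaluation is unavailable; the
  study's beat inventory (19,320 N / 2,941 R / 813 P / 238 W / 10 V / 5 S)
  cannot be rebuilt, and classes W and S remain label-only here exactly
  because such data are too scarce to train on.
* The published McNemar p = 0.004 compares two classifiers on the real
  48-child cohort; the discordant-pair cells were not printed, so that
  p-value is not recomputable from public information. The test suite
  instead proves the test statistic itself against brute-force
  enumeration.
* The winning hyperparameter configuration of the original tuning run and
  the trained Xception_v8 weights are not public; this package ships the
  architecture families and the search machinery, not the artifact.
* Accuracy numbers reported by the tests and the acceptance script are
  measured on synthetic data and bound the machinery, not clinical
  performance.
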