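# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ecglvh`. The package re-implements, end to end, an analysis
chain that predicts indexed left-ventricular mass (iLVM, g/m²) and
left-ventricular hypertrophy (LVH) from resting multi-lead ECGs and clinical
covariates, and exercises the whole chain on a synthetic cohort whose
structure mirrors a population imaging study.

## Clinical definitions

Body surface area uses the Mosteller formula, BSA = √(height·weight/3600)
(cm, kg → m²); iLVM = LVM/BSA. LVH is defined by strict sex-specific
thresholds: iLVM > 70 g/m² for males, > 55 g/m² for females. Blood pressure
of medicated participants is adjusted by +15/+10 mmHg (systolic/diastolic);
total and non-HDL cholesterol of statin-treated participants are divided by
0.73 and 0.66. Hypertension is a diagnosis, BP medication, or adjusted BP
exceeding 130/85 mmHg; diabetes is HbA1c ≥ 48 mmol/mol; hypercholesterolaemia
is adjusted total cholesterol ≥ 5 mmol/L. The hypertension rule applies the
*adjusted* pressures by default (configurable via `derive_conditions(...,
use_adjusted_bp=False)`); the alternative reading (raw pressures) changes the
flag only for medicated participants whose raw BP sits within 15/10 mmHg of
the cut-off, and those participants are already hypertensive through the
medication clause, so the choice is nearly consequence-free.

Cohort splits (70/15/15 by default, 60/20/20 for external-style evaluation)
are seeded uniform shuffles with largest-remainder sizing; splits are not
stratified by LVH by default, with a `stratify_labels` option.

## Median-beat extraction

Raw recordings (any rate > 90 Hz; linearly resampled to 500 Hz) are band-pass
filtered 1–45 Hz with a 4th-order Butterworth applied forward–backward (zero
phase). R peaks are detected on the first principal component of the eight
leads: the component is additionally band-passed to the QRS energy band
(8–25 Hz) and rectified — a plain rectified principal component produces
T-wave false positives — thresholded at 0.5 × the chunkwise (2 s) 95th
percentile with a 250 ms refractory period, and each candidate is refined to
the broadband extremum within ±40 ms.

Beats are windowed over [−400 ms, +800 ms) around the R peak (1.2 s,
L = 600 samples at 500 Hz). Each beat is aligned to a robust template — the
pointwise median of all candidate windows, which tolerates any minority of
artefact beats including a corrupted first beat — by the lag within ±50 ms
maximizing the normalized cross-correlation over the concatenated leads.
Beats whose maximal correlation falls below 0.8 are rejected. The final beat
is the pointwise **25% trimmed mean** of the retained aligned windows: the
trimmed mean keeps near-mean noise efficiency while remaining robust to
artefact-beat tails that genuinely overlap neighbouring windows when the R-R
interval is shorter than the window. The mean R-R interval is computed over
consecutive retained beats and the ventricular rate is 60000/RR.

Two numerical facts worth knowing. First, at R-R < 1200 ms the 1.2 s window
necessarily contains tails of neighbouring beats; the faithful ground truth
for recovery checks is therefore the noiseless *periodic* beat window
(`cohort.expected_beat_window`), not the isolated single-beat template.
Second, the 1 Hz high-pass edge transient of a finite 15 s recording leaves
~10⁻⁴ mV discrepancies between nominally identical beat windows; extraction
cannot be exact below that floor, and the idempotence test asserts recovery
at 5×10⁻⁴ mV (three orders of magnitude below signal scale).

## Feature assembly

The network input is the 8 × L median beat in millivolts plus a fixed-order
15-entry metadata vector: age, sex, BMI, adjusted SBP/DBP, hypertension,
diabetes, hypercholesterolaemia, adjusted total and non-HDL cholesterol,
alcohol status, smoking one-hot (never/previous/current), and ventricular
rate — the single ECG-derived biomarker. Continuous features are min–max
normalized against the training partition only (values outside the training
range extrapolate linearly; no clipping); binary features pass through.
Missing values are imputed with the column median (continuous) or mode
(binary/categorical) within the cohort being processed.

Signal processing, beat storage and voltage-criteria measurement stay at
500 Hz; the network input is decimated to 100 Hz (L = 120) by sample picking,
which is alias-free because the beat is already band-limited to 45 Hz. This
keeps CPU training fast without discarding in-band information; the network's
parameter count is independent of L (global average pooling).

## Network, loss, training

The regressor/classifier is a fully convolutional network implemented in
numpy (the package carries its own layer stack, hand-written backward passes
verified against finite differences to ~10⁻⁸, and an Adam optimizer):

    3 × [Conv1d (128×8, 256×5, 128×3) → BatchNorm → ReLU → MaxPool(2)]
    → Dropout 0.4 → GlobalAveragePool → concat(metadata, 15)
    → Dense 128 → ReLU → Dropout 0.6 → Dense 1

290,433 trainable parameters with the default configuration. The regression
head is linear and trained with the log-cosh loss (quadratic near zero,
linear in the tails — robust to the right-skewed mass distribution), in the
overflow-safe form |x| + log1p(e^{−2|x|}) − log 2; the classification
variant uses a sigmoid head with binary cross-entropy (the standard choice
for a sigmoid output; assumption documented here). Unstated architectural
details are pinned as: ReLU activations, max-pool kernel/stride 2, 128-unit
hidden layer — chosen so the total parameter count lands on the published
~293k order.

Training: Adam, learning rate 5·10⁻⁴, batch 64, up to 200 epochs with early
stopping after 20 epochs without validation-loss improvement (strict decrease
by ≥ 10⁻⁶) and learning-rate reduction ×0.1 after 10; best-validation weights
are restored at the end. The regression head's bias is initialized to the
training-target mean — with a loss that is linear in large residuals, Adam's
bounded steps would otherwise spend tens of thousands of updates moving the
output level to ~45 g/m². All randomness flows through seeded generators;
two runs with the same seed produce identical loss traces.

Fine-tuning for a shifted cohort unfreezes the post-pooling head first
(lr 5·10⁻⁵, weight decay 10⁻⁴) and then the convolutional blocks one at a
time, deepest first (lr 10⁻⁴, weight decay 10⁻⁵), with morphology-preserving
training-batch augmentation: random end-crops up to 25 samples with linear
re-interpolation to L, per-lead Gaussian noise (SD 0.005 mV), and a common
amplitude scale drawn from [0.9, 1.1]. Frozen blocks also freeze their
batch-norm running statistics, so their inference behaviour is bit-stable.

## LVH decisions

Three classification routes are implemented. (1) Threshold the predicted
iLVM at the published 70/55 g/m² cut-offs — sensitive to the systematic
underestimation a skewed training distribution induces. (2) Recalibration: a
logistic regression of the true label on (predicted iLVM, sex) with balanced
class weights n/(2·n_class), fitted with sklearn on internally standardized
inputs (inverse ridge strength C = 10⁴, i.e. effectively unpenalized);
coefficients are mapped back to g/m², implying adaptive cut-offs
−(β₀+β_sex·sex)/β_iLVM where the class probability crosses 0.5. The
recalibration is fitted on the *validation* split's predictions in the
pipeline. (3) The classical voltage criteria from the median beat:
Sokolow–Lyon S_V1 + max(R_V5, R_V6) ≥ 3.5 mV and Cornell voltage
R_aVL + S_V3 > 2.8 mV (men) / > 2.0 mV (women), with aVL reconstructed from
the limb leads as I − II/2, amplitudes measured within ±80 ms of the
alignment point after subtracting a baseline estimated from the first 100 ms
of the window. Boundary conventions (≥ for Sokolow–Lyon, strict > for
Cornell) follow the cited clinical definitions and are pinned in code.

## Evaluation statistics

AUROC is the Mann–Whitney pair-counting statistic (computed through
midranks; exactly equal to brute-force counting with half-credit ties), with
the Hanley–McNeil analytic 95% CI. Paired AUROCs are compared with the fast
midrank DeLong test; the implementation matches R's pROC to ~10⁻⁹ relative.
At n = 20 DeLong's normal approximation tracks an exact sign-flip permutation
reference to within a couple of percent for null-like instances; for extreme
instances the approximation error itself can exceed 0.02 — a property of the
asymptotic test, not of the implementation. Operating points maximize
Youden's J over all score midpoints (ties resolved toward higher
specificity); sensitivity/specificity CIs are Wilson score intervals (the
interval family is not dictated by the analysis being reproduced; Wilson is
chosen for small-count robustness). Regression accuracy reports MAE and ME
(prediction − observation, so underestimation is negative) with seeded
5000-replicate percentile-bootstrap CIs, Pearson r, an OLS fit with adjusted
R², and the residual skew. Bland–Altman agreement reports bias ± 1.96 SD with
t-based CIs on each limit (half-width t₀.₉₇₅,ₙ₋₁·√(3s²/n)).

## Explainability

Integrated gradients attribute a prediction to every ECG sample and metadata
entry: for each baseline x′ from a background sample (default 1000 in
full-scale use; tests use 16–64 for speed), a midpoint Riemann sum over 50
steps (default) approximates (x−x′)⊙∫∇F; attributions are averaged over
baselines and the completeness residual |Σa − (F(x) − mean F(x′))| is
recorded. Closed-form exactness on linear models and ≤1% completeness on the
trained network (200 steps) are tested. Group contrasts report mean ± SD
waveforms for participants below the 5th / above the 95th percentile of
predicted iLVM.

## The synthetic cohort

The generator emulates the *structure* of the study data, not its biology.
Each participant draws sex (51.8% female), then iLVM from a per-sex
log-normal whose log-scale is 0.20 and whose log-location is calibrated
analytically so that P(iLVM > threshold) equals the prevalence target
(1.5% by default; 5.8% in the external-style preset) — giving means ≈ 46/41
g/m² and SD ≈ 9, consistent with the published baseline table. The beat is a
sum of Gaussian waves (P, Q, R, S, T) with fixed per-lead polarities (V1
net-negative QRS, V5/V6 net-positive); QRS amplitudes scale multiplicatively
so the reference-lead (V5) R amplitude grows at 0.02 mV per g/m² above the
sex reference mean, QRS widths grow at 0.1 ms/(g/m²), and the T-wave centre
shortens with heart rate (√ law). Raw recordings are 15 s at 500 Hz: beats at
R-R = 60000/HR ms with 15 ms Gaussian jitter, Gaussian sensor noise (SD
0.05 mV), sub-1 Hz sinusoidal baseline wander (0.05 mV), and 20% of beats
replaced by an inverted, width-doubled morphology for rejection testing.
Heart rate is drawn per LVH stratum (59.3 ± 10.8 vs 61.7 ± 10.2 bpm).
Covariates are drawn per stratum from the published table's means/SDs with
physiological clamps; HbA1c is calibrated so P(≥48) reproduces the printed
diabetes prevalences; medication-flag rates are package choices. Two presets
modify the defaults: an external-style cohort (−13 years, 5.8% prevalence,
lower BP, different smoking mix, 250 Hz acquisition, 1.5× amplitude
coupling) and a zero-signal null cohort (all slopes zero, stratum
distributions identical) whose trained-model AUROC must be chance. The null
check uses the 5.8% prevalence and a large test share so the chance-level
AUROC estimate has SE ≈ 0.026; at 1.5% prevalence the estimate's noise would
swamp the question.

What passing the synthetic tests does **not** show: recovery of real ECG
morphology (no vectorcardiographic model, no arrhythmia, no pediatric or
athlete phenotypes), realistic covariate–ECG correlation structure, or the
published cohort performance numbers, which require access-restricted data.
The synthetic experiments demonstrate that the pipeline's machinery —
averaging, rejection, training, recalibration, statistics — does what it
claims under known ground truth.

## Problem sizes used in tests and the acceptance script

The shipped experiments are sized for a single CPU: end-to-end parameter
recovery trains on 2000 participants (median-beat preprocessing included)
with a 60-epoch cap; the null check uses 4000 participants with a 55% test
share; median-beat recovery uses 100 recordings at ~60 bpm (15 beats per
recording, matching the worked examples); oracle equivalence uses 1000
random instances per statistic. These sizes are the package's defaults for
its own verification and can be scaled up through the same configuration
objects.

## Known limitations

- The EDF writer is minimal (16-bit, one-second records, integer sampling
  rates); reading goes through MNE. Physical-dimension handling follows the
  EDF convention of scaling to the declared physical range.
- The FCN is CPU-bound numpy; it is fast enough for the desk-scale cohorts
  here but not intended for 50k-participant training.
- The recalibration's implied cut-offs assume β_iLVM > 0; a no-signal model
  yields a non-monotone recalibration and the pipeline reports absent
  cut-offs rather than fabricating them.
- Under perfectly separable labels the logistic recalibration is fitted with
  a large-but-finite C; recovered cut-offs are accurate to well under
  1 g/m², but the coefficients themselves are scale-unstable in that regime
  (as for any unpenalized logistic fit on separable data).
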