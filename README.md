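# ecglvh

Left-ventricular hypertrophy (LVH) — thickening of the left-ventricular
myocardium — is a strong, treatable cardiovascular risk factor, but the
standard 12-lead ECG detects it poorly: classical voltage criteria
(Sokolow–Lyon, Cornell) have high specificity and very low sensitivity.
`ecglvh` implements a complete analysis chain that predicts cardiac-MRI-grade
indexed left-ventricular mass (iLVM, g/m²) directly from the ECG:

1. **Median-beat extraction** — band-pass filtering (1–45 Hz, zero phase),
   R-peak detection on the leads' first principal component, beat alignment
   by time-lagged normalized cross-correlation with rejection of uncorrelated
   beats, and robust averaging into one representative beat per lead, plus the
   ventricular rate from the mean R-R interval.
2. **Clinical covariates** — Mosteller body-surface-area indexing
   (BSA = √(h·w/3600)), sex-specific LVH labels (iLVM > 70 g/m² male,
   > 55 g/m² female), medication adjustments (+15/+10 mmHg BP; cholesterol
   ÷0.73/÷0.66) and derived condition flags.
3. **A fully convolutional network** (three conv blocks 128×8/256×5/128×3
   with batch-norm and max-pooling, global average pooling, concatenation
   with 15 clinical metadata entries, ≈2.9×10⁵ parameters) trained with the
   log-cosh loss to regress iLVM; implemented in numpy, CPU-only,
   deterministic under a seed.
4. **Recalibration** — a class-balanced logistic regression of LVH on
   (predicted iLVM, sex) that converts biased regression output into
   calibrated decisions with *adaptive* sex-specific iLVM cut-offs
   −(β₀+β_sex·sex)/β_iLVM.
5. **Evaluation statistics** — AUROC with Hanley–McNeil analytic CIs, the
   fast DeLong test, Youden-J operating points, Wilson CIs for
   sensitivity/specificity, bootstrap MAE/ME intervals, OLS and Bland–Altman
   agreement — and **integrated-gradients** explainability with background
   averaging and completeness checks.
6. **A synthetic-cohort generator** that emulates the statistical structure
   of a population imaging study (right-skewed per-sex iLVM with calibrated
   LVH prevalence, QRS morphology that encodes the latent mass, LVH-shifted
   covariates, noisy 15 s raw recordings with corrupted beats), so the whole
   chain is testable end to end without access-restricted data.

The intended users are methods researchers in biomedical signal analysis and
clinical prediction modelling who need a transparent, fully testable
reference implementation of this pipeline.

## Worked example

```bash
python examples/train_and_evaluate.py
```

trains the network on a 500-participant synthetic cohort (10% LVH prevalence
so the example is statistically readable at small n) and prints:

```
held-out iLVM regression: r = 0.972, MAE = 2.77 g/m^2 (ME -0.83: negative means systematic underestimation)
recalibrated LVH classification: AUROC = 1.000 (95% CI 1.000-1.000)
Youden operating point: sensitivity 1.00, specificity 1.00
adaptive iLVM cut-offs from the recalibration: male 64.3, female 57.6 g/m^2 (vs the 70/55 reference values; shifted to compensate prediction bias)
fixed 70/55 thresholds for comparison: sensitivity 0.86, specificity 1.00
```

Read: the network recovers the latent mass well (r ≈ 0.97) with a negative
mean error — trained on a skewed distribution it under-predicts, so the
logistic recalibration settles on sex-specific cut-offs below its *predicted*
masses' reference values and separates the held-out cases cleanly (at this
desk scale the test split is small enough for a perfect AUROC; the analytic
CI is degenerate there and the package logs a warning saying so). The fixed
70/55 g/m² thresholds already lose one in seven cases to the
under-prediction. The other example scripts
(`examples/*.py`) demonstrate cohort generation, median-beat extraction,
the voltage-criteria benchmarks and integrated-gradients explainability.

A thin CLI wraps the pipeline for batch use:

```bash
ecglvh simulate --seed 1 --n-participants 100 --out scratch/demo
ecglvh full-run --seed 1 --n-participants 500 --out scratch/run
```

## Layout

```
src/ecglvh/
  cohort.py         synthetic-cohort generator and presets
  preprocessing.py  filtering, R-peak detection, median beats, normalization
  clinical.py       BSA/iLVM indexing, adjustments, conditions, splits
  nn.py, model.py   numpy FCN, Adam, training/fine-tuning, augmentation
  classify.py       thresholds, logistic recalibration, voltage criteria
  stats.py          AUROC/DeLong/Youden/bootstrap/Bland-Altman
  explain.py        integrated gradients, importance summaries
  pipeline.py       end-to-end orchestration and artifacts
  io.py             columnar-text and EDF ECG I/O
docs/methods.md     model and parameter documentation
examples/           one narrative script per capability
```
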