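"""LVH decision rules: reference thresholds, logistic recalibration, and
classical ECG voltage criteria.

A regression model that systematically underestimates indexed LV mass loses
sensitivity when its predictions are thresholded at the published reference
cut-offs (70 g/m^2 male / 55 g/m^2 female). The recalibration step fits a
class-weight-balanced logistic regression of the true LVH label on (predicted
iLVM, sex); because the linear predictor is monotone in iLVM, the fitted
coefficients imply adaptive sex-specific iLVM cut-offs, namely the predicted
mass at which the class probability crosses 0.5.

The classical voltage criteria are computed from the median beat:
Sokolow-Lyon S_V1 + max(R_V5, R_V6) >= 3.5 mV, and Cornell voltage
R_aVL + S_V3 > 2.8 mV (men) / > 2.0 mV (women), with aVL derived from the
limb leads as I - II/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .clinical import FEMALE, MALE, lvh_from_ilvm
from .core import MedianBeat
from .errors import FitError, InvalidArgumentError

SOKOLOW_LYON_THRESHOLD_MV = 3.5
CORNELL_THRESHOLD_MV = {MALE: 2.8, FEMALE: 2.0}

#: QRS measurement window around the alignment point, and baseline segment.
QRS_WINDOW_MS = 80.0
BASELINE_SEGMENT_MS = 100.0


def classify_by_reference_threshold(predicted_ilvm, sex):
    """LVH flag from predicted iLVM at the published sex-specific cut-offs."""
    predicted_ilvm = np.asarray(predicted_ilvm, dtype=float)
    if not np.isfinite(predicted_ilvm).all():
        raise InvalidArgumentError("predicted iLVM must be finite")
    return lvh_from_ilvm(predicted_ilvm, sex)


@dataclass
class RecalibrationModel:
    """Logistic recalibration of iLVM predictions with a sex covariate."""

    intercept: float
    coef_ilvm: float
    coef_sex: float
    fitted_on: str = ""

    def linear_predictor(self, predicted_ilvm, sex):
        return (self.intercept
                + self.coef_ilvm * np.asarray(predicted_ilvm, dtype=float)
                + self.coef_sex * np.asarray(sex, dtype=float))

    def probability(self, predicted_ilvm, sex):
        z = self.linear_predictor(predicted_ilvm, sex)
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def classify(self, predicted_ilvm, sex, probability_cutoff: float = 0.5):
        return self.probability(predicted_ilvm, sex) > probability_cutoff

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "intercept": self.intercept,
                "coef_ilvm": self.coef_ilvm,
                "coef_sex": self.coef_sex,
                "fitted_on": self.fitted_on,
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RecalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_recalibration(
    predicted_ilvm,
    sex,
    true_lvh_labels,
    fitted_on: str = "",
    C: float = 1e4,
) -> RecalibrationModel:
    """Fit the class-weight-balanced logistic regression on (iLVM, sex).

    Sample weights follow the balanced scheme n / (2 * n_class). Inputs are
    standardized internally for solver conditioning; coefficients are mapped
    back to the g/m^2 scale. ``C`` is the inverse ridge strength — large by
    default so the fit is effectively the (weighted) maximum-likelihood one.
    """
    x = np.column_stack([
        np.asarray(predicted_ilvm, dtype=float),
        np.asarray(sex, dtype=float),
    ])
    y = np.asarray(true_lvh_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise FitError("both classes must be present to fit the recalibration")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    lr = LogisticRegression(class_weight="balanced", C=C, max_iter=5000,
                            solver="lbfgs")
    lr.fit(xs, y)
    if lr.n_iter_[0] >= 5000:
        raise FitError("recalibration fit did not converge")
    coef = lr.coef_[0] / sd
    intercept = float(lr.intercept_[0] - np.sum(lr.coef_[0] * mu / sd))
    return RecalibrationModel(
        intercept=intercept,
        coef_ilvm=float(coef[0]),
        coef_sex=float(coef[1]),
        fitted_on=fitted_on,
    )


def cutoffs_from_recalibration(model: RecalibrationModel) -> tuple[float, float]:
    """(male, female) iLVM cut-offs where the recalibrated probability is 0.5."""
    if model.coef_ilvm <= 0:
        raise FitError(
            "recalibration is not monotone-increasing in iLVM "
            f"(coef_ilvm={model.coef_ilvm:.4g})"
        )
    male = -(model.intercept + model.coef_sex * MALE) / model.coef_ilvm
    female = -(model.intercept + model.coef_sex * FEMALE) / model.coef_ilvm
    return float(male), float(female)


# ---------------------------------------------------------------------------
# voltage criteria

@dataclass(frozen=True)
class VoltageMeasurements:
    """R amplitudes and S depths (both stored positive, mV) per needed lead."""

    r_amplitude: dict  # lead -> mV
    s_depth: dict  # lead -> mV (depth below baseline, >= 0)

    def __post_init__(self):
        if any(v < 0 for v in self.s_depth.values()):
            raise InvalidArgumentError("S depths must be stored non-negative")


def _measure_lead(signal: np.ndarray, fs: float, r_sample: int) -> tuple[float, float]:
    """(R amplitude, S depth) inside the QRS window, baseline-corrected."""
    baseline = float(np.median(signal[: max(round(BASELINE_SEGMENT_MS / 1000 * fs), 1)]))
    half = round(QRS_WINDOW_MS / 1000 * fs)
    lo, hi = r_sample - half, r_sample + half + 1
    if lo < 0 or hi > signal.size:
        raise InvalidArgumentError("QRS window falls outside the beat window")
    window = signal[lo:hi] - baseline
    r_idx = int(np.argmax(window))
    r_amp = max(float(window[r_idx]), 0.0)
    after = window[r_idx:]
    s_depth = max(float(-(after.min())), 0.0) if after.size else 0.0
    return r_amp, s_depth


def measure_wave_amplitudes(beat: MedianBeat) -> VoltageMeasurements:
    """R/S amplitudes for V1, V3, V5, V6 and the derived aVL lead.

    aVL is reconstructed samplewise from the limb leads (aVL = I - II/2)
    before measurement; the baseline is the median of the earliest 100 ms of
    the beat window.
    """
    fs = beat.sampling_rate_hz
    leads = {name: beat.lead(name) for name in ("V1", "V3", "V5", "V6")}
    leads["aVL"] = beat.lead("I") - beat.lead("II") / 2.0
    r_amp, s_depth = {}, {}
    for name, signal in leads.items():
        r_amp[name], s_depth[name] = _measure_lead(signal, fs, beat.r_sample)
    return VoltageMeasurements(r_amplitude=r_amp, s_depth=s_depth)


def sokolow_lyon(v: VoltageMeasurements) -> tuple[float, bool]:
    """S_V1 + max(R_V5, R_V6); positive at >= 3.5 mV."""
    for lead in ("V1", "V5", "V6"):
        if lead not in v.r_amplitude:
            raise InvalidArgumentError(f"lead {lead} not measured")
    index = v.s_depth["V1"] + max(v.r_amplitude["V5"], v.r_amplitude["V6"])
    return float(index), bool(index >= SOKOLOW_LYON_THRESHOLD_MV)


def cornell_voltage(v: VoltageMeasurements, sex: int) -> tuple[float, bool]:
    """R_aVL + S_V3; positive at > 2.8 mV (male) / > 2.0 mV (female)."""
    if sex not in CORNELL_THRESHOLD_MV:
        raise InvalidArgumentError("sex must be coded 0 (female) / 1 (male)")
    for lead in ("aVL", "V3"):
        if lead not in v.r_amplitude:
            raise InvalidArgumentError(f"lead {lead} not measured")
    index = v.r_amplitude["aVL"] + v.s_depth["V3"]
    return float(index), bool(index > CORNELL_THRESHOLD_MV[sex])
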