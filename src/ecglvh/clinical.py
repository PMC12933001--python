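"""Clinical covariates, CMR indexing and cohort splitting.

Implements the clinical side of the analysis: body-surface-area indexing of
left-ventricular mass (Mosteller), sex-specific hypertrophy labelling,
treatment adjustments for blood pressure and cholesterol, derived condition
flags (hypertension, diabetes, hypercholesterolaemia) and reproducible
train/validation/test splits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

#: Sex encoding used throughout the package.
FEMALE, MALE = 0, 1

#: Sex-specific indexed-LVM thresholds (g/m^2) above which LVH is diagnosed.
LVH_THRESHOLD_MALE = 70.0
LVH_THRESHOLD_FEMALE = 55.0

SMOKING_LEVELS = ("never", "previous", "current")


@dataclass
class ClinicalProfile:
    """Raw and derived per-participant covariates (the model "metadata")."""

    participant_id: str
    age: float
    sex: int  # 0 = female, 1 = male
    bmi: float
    sbp_raw: float
    dbp_raw: float
    on_bp_medication: bool
    total_chol_raw: float
    non_hdl_raw: float
    on_lipid_medication: bool
    hba1c: float
    smoking: str  # never / previous / current
    alcohol: int  # 0 = never, 1 = current
    hypertension_dx: bool = False
    # adjusted / derived fields, filled by adjust_* and derive_conditions
    sbp_adj: float | None = None
    dbp_adj: float | None = None
    total_chol_adj: float | None = None
    non_hdl_adj: float | None = None
    hypertension: bool | None = None
    diabetes: bool | None = None
    hypercholesterolaemia: bool | None = None
    ventricular_rate_bpm: float | None = None


@dataclass(frozen=True)
class CmrMeasurement:
    """CMR-derived mass, indexing anthropometry and the LVH ground truth."""

    participant_id: str
    lvm_g: float
    height_cm: float
    weight_kg: float
    bsa_m2: float
    ilvm: float
    lvh_label: bool


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        all_ids = set(self.train_ids) | set(self.validation_ids) | set(self.test_ids)
        n = len(self.train_ids) + len(self.validation_ids) + len(self.test_ids)
        if len(all_ids) != n:
            raise InvalidArgumentError("split partitions are not disjoint")


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise InvalidArgumentError(
            f"height and weight must be positive, got {height_cm}, {weight_kg}"
        )
    return math.sqrt(height_cm * weight_kg / 3600.0)


def lvh_from_ilvm(ilvm, sex):
    """Sex-specific LVH rule: strict > 70 g/m^2 (male) / > 55 g/m^2 (female).

    Works elementwise on arrays.
    """
    ilvm = np.asarray(ilvm, dtype=float)
    sex = np.asarray(sex)
    if not np.isin(sex, (FEMALE, MALE)).all():
        raise InvalidArgumentError("sex must be coded 0 (female) / 1 (male)")
    thr = np.where(sex == MALE, LVH_THRESHOLD_MALE, LVH_THRESHOLD_FEMALE)
    out = ilvm > thr
    return bool(out) if out.ndim == 0 else out


def index_and_label(
    participant_id: str, lvm_g: float, height_cm: float, weight_kg: float, sex: int
) -> CmrMeasurement:
    """Index LVM by Mosteller BSA and apply the sex-specific LVH threshold."""
    if lvm_g <= 0:
        raise InvalidArgumentError(f"lvm_g must be positive, got {lvm_g}")
    bsa = mosteller_bsa(height_cm, weight_kg)
    ilvm = lvm_g / bsa
    return CmrMeasurement(
        participant_id=participant_id,
        lvm_g=lvm_g,
        height_cm=height_cm,
        weight_kg=weight_kg,
        bsa_m2=bsa,
        ilvm=ilvm,
        lvh_label=lvh_from_ilvm(ilvm, sex),
    )


def adjust_bp(
    sbp_raw: float, dbp_raw: float, on_bp_medication: bool
) -> tuple[float, float]:
    """Add 15/10 mmHg to systolic/diastolic BP for medicated participants."""
    if not (70 <= sbp_raw <= 300) or not (30 <= dbp_raw <= 200):
        logger.warning(
            "BP reading outside physiological range: %s/%s", sbp_raw, dbp_raw
        )
    if on_bp_medication:
        return sbp_raw + 15.0, dbp_raw + 10.0
    return sbp_raw, dbp_raw


def adjust_cholesterol(
    total_raw: float, non_hdl_raw: float, on_lipid_medication: bool
) -> tuple[float, float]:
    """Divide total / non-HDL cholesterol by 0.73 / 0.66 for medicated participants."""
    if total_raw <= 0 or non_hdl_raw <= 0:
        raise InvalidArgumentError("cholesterol values must be positive")
    if on_lipid_medication:
        return total_raw / 0.73, non_hdl_raw / 0.66
    return total_raw, non_hdl_raw


def apply_adjustments(profile: ClinicalProfile) -> ClinicalProfile:
    """Fill the treatment-adjusted BP and cholesterol fields (idempotent)."""
    sbp_adj, dbp_adj = adjust_bp(
        profile.sbp_raw, profile.dbp_raw, profile.on_bp_medication
    )
    tot_adj, nh_adj = adjust_cholesterol(
        profile.total_chol_raw, profile.non_hdl_raw, profile.on_lipid_medication
    )
    return replace(
        profile,
        sbp_adj=sbp_adj,
        dbp_adj=dbp_adj,
        total_chol_adj=tot_adj,
        non_hdl_adj=nh_adj,
    )


def derive_conditions(profile: ClinicalProfile, use_adjusted_bp: bool = True) -> ClinicalProfile:
    """Set hypertension / diabetes / hypercholesterolaemia flags.

    Hypertension: formal diagnosis, BP medication, or BP exceeding 130/85 mmHg
    (adjusted readings by default). Diabetes: HbA1c >= 48 mmol/mol.
    Hypercholesterolaemia: adjusted total cholesterol >= 5 mmol/L.
    """
    if profile.sbp_adj is None or profile.total_chol_adj is None:
        raise InvalidArgumentError(
            "adjustments must be applied before deriving conditions"
        )
    sbp = profile.sbp_adj if use_adjusted_bp else profile.sbp_raw
    dbp = profile.dbp_adj if use_adjusted_bp else profile.dbp_raw
    hypertension = (
        bool(profile.hypertension_dx)
        or bool(profile.on_bp_medication)
        or sbp > 130.0
        or dbp > 85.0
    )
    return replace(
        profile,
        hypertension=hypertension,
        diabetes=profile.hba1c >= 48.0,
        hypercholesterolaemia=profile.total_chol_adj >= 5.0,
    )


def prepare_profile(profile: ClinicalProfile) -> ClinicalProfile:
    """adjust -> derive pipeline; safe to call repeatedly (adjusts raw fields once)."""
    return derive_conditions(apply_adjustments(profile))


def split_cohort(
    ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratify_labels: Sequence[bool] | None = None,
) -> CohortSplit:
    """Seeded random train/validation/test partition.

    Sizes follow the largest-remainder rule, so realized fractions are within
    one participant of the targets. With ``stratify_labels`` the partition is
    performed within each label stratum (optional; default simple random).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"fractions must sum to 1, got {fractions}")
    ids = list(ids)
    rng = np.random.default_rng(seed)

    def _partition(sub_ids: list[str]) -> tuple[list[str], list[str], list[str]]:
        perm = rng.permutation(len(sub_ids))
        shuffled = [sub_ids[i] for i in perm]
        n = len(sub_ids)
        raw = [f * n for f in fractions]
        sizes = [int(math.floor(r)) for r in raw]
        remainders = [r - s for r, s in zip(raw, sizes)]
        for i in np.argsort(remainders)[::-1][: n - sum(sizes)]:
            sizes[i] += 1
        a, b = sizes[0], sizes[0] + sizes[1]
        return shuffled[:a], shuffled[a:b], shuffled[b:]

    if stratify_labels is None:
        tr, va, te = _partition(ids)
    else:
        labels = list(stratify_labels)
        tr, va, te = [], [], []
        for value in sorted({*labels}):
            sub = [i for i, lab in zip(ids, labels) if lab == value]
            a, b, c = _partition(sub)
            tr += a
            va += b
            te += c
    return CohortSplit(tuple(tr), tuple(va), tuple(te), tuple(fractions), seed)


# ---------------------------------------------------------------------------
# tabular round-trips

PROFILE_COLUMNS = [
    "participant_id", "age", "sex", "bmi", "sbp_raw", "dbp_raw",
    "on_bp_medication", "hypertension_dx", "total_chol_raw", "non_hdl_raw",
    "on_lipid_medication", "hba1c", "smoking", "alcohol",
    "sbp_adj", "dbp_adj", "total_chol_adj", "non_hdl_adj",
    "hypertension", "diabetes", "hypercholesterolaemia", "ventricular_rate_bpm",
]

CMR_COLUMNS = [
    "participant_id", "lvm_g", "height_cm", "weight_kg", "bsa_m2", "ilvm",
    "lvh_label",
]


def profiles_to_frame(profiles: Sequence[ClinicalProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(p, c) for c in PROFILE_COLUMNS} for p in profiles]
    )


def frame_to_profiles(frame: pd.DataFrame) -> list[ClinicalProfile]:
    profiles = []
    for row in frame.to_dict("records"):
        kwargs = {c: row[c] for c in PROFILE_COLUMNS if c in row}
        for flag in ("on_bp_medication", "on_lipid_medication", "hypertension_dx"):
            kwargs[flag] = bool(kwargs[flag])
        kwargs["sex"] = int(kwargs["sex"])
        kwargs["alcohol"] = int(kwargs["alcohol"])
        for opt in ("hypertension", "diabetes", "hypercholesterolaemia"):
            if opt in kwargs and pd.notna(kwargs[opt]):
                kwargs[opt] = bool(kwargs[opt])
            else:
                kwargs[opt] = None
        for opt in ("sbp_adj", "dbp_adj", "total_chol_adj", "non_hdl_adj",
                    "ventricular_rate_bpm"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        profiles.append(ClinicalProfile(**kwargs))
    return profiles


def cmr_to_frame(measurements: Sequence[CmrMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(m, c) for c in CMR_COLUMNS} for m in measurements]
    )


def write_clinical_csv(profiles: Sequence[ClinicalProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_clinical_csv(path) -> list[ClinicalProfile]:
    return frame_to_profiles(pd.read_csv(path))


def write_cmr_csv(measurements: Sequence[CmrMeasurement], path) -> None:
    cmr_to_frame(measurements).to_csv(path, index=False)


def read_cmr_csv(path) -> list[CmrMeasurement]:
    frame = pd.read_csv(path)
    return [
        CmrMeasurement(
            participant_id=str(r["participant_id"]),
            lvm_g=float(r["lvm_g"]),
            height_cm=float(r["height_cm"]),
            weight_kg=float(r["weight_kg"]),
            bsa_m2=float(r["bsa_m2"]),
            ilvm=float(r["ilvm"]),
            lvh_label=bool(r["lvh_label"]),
        )
        for r in frame.to_dict("records")
    ]
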