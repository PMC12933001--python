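"""Shared fixtures: the two expensive end-to-end experiments are session-scoped
so parameter-recovery, explainability and acceptance checks reuse one training
run each."""

from __future__ import annotations

import pytest

from ecglvh.cohort import SyntheticCohortConfig, null_cohort_config
from ecglvh.pipeline import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def signal_experiment():
    """Default synthetic cohort (n=2000, full effect sizes), trained FCN_LVM."""
    cfg = ExperimentConfig(
        cohort=SyntheticCohortConfig(n_participants=2000),
        max_epochs=60,
        seed=101,
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def null_experiment():
    """Zero-effect-size cohort: no QRS, rate or covariate differences by label.

    The model is the ECG-only (metadata-excluded) variant: even with all
    effect slopes at zero, sex in the metadata legitimately predicts
    *continuous* iLVM (the per-sex distributions differ), which is exactly
    the signal the null check must exclude. A larger test share gives the
    chance-level AUROC estimate a usefully small standard error (~0.026 with
    ~120 positives).
    """
    cfg = ExperimentConfig(
        cohort=null_cohort_config(n_participants=4000),
        split_fractions=(0.35, 0.10, 0.55),
        include_metadata=False,
        max_epochs=60,
        seed=202,
    )
    return run_experiment(cfg)
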