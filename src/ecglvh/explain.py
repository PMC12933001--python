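"""Model explainability: integrated gradients and group waveform contrasts.

Integrated gradients attribute a differentiable model's output to each input
element by integrating the gradient along the straight path from a baseline
to the input and scaling by the input-baseline difference. Attributions are
averaged over a random background sample of participants (default 1000 in
full-scale analyses) to stabilize the baseline choice, and satisfy the
completeness axiom: summed attributions approach F(x) minus the mean baseline
prediction as the path discretization is refined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EcgLvhError, GroupingError, InvalidArgumentError
from .model import FCN
from .preprocessing import METADATA_MANIFEST, FeatureVector

#: Default number of Riemann (midpoint) steps along the path.
DEFAULT_STEPS = 50


@dataclass
class AttributionMap:
    participant_id: str
    ecg_attributions: np.ndarray  # (8, L), signed
    metadata_attributions: np.ndarray | None  # (15,), signed
    n_background: int
    baseline_prediction_mean: float
    prediction: float
    n_path_steps: int
    completeness_residual: float

    @property
    def total_attribution(self) -> float:
        total = float(self.ecg_attributions.sum())
        if self.metadata_attributions is not None:
            total += float(self.metadata_attributions.sum())
        return total


def _as_arrays(item) -> tuple[np.ndarray, np.ndarray | None, str]:
    if isinstance(item, FeatureVector):
        return np.asarray(item.ecg, float), np.asarray(item.metadata, float), item.participant_id
    ecg, meta = item
    return np.asarray(ecg, float), (None if meta is None else np.asarray(meta, float)), ""


def integrated_gradients(
    model: FCN,
    input_sample,
    background,
    steps: int = DEFAULT_STEPS,
) -> AttributionMap:
    """Attribution of one prediction relative to a background sample.

    ``input_sample`` is a FeatureVector or an (ecg, metadata) pair;
    ``background`` a sequence of the same. For each baseline x', the midpoint
    Riemann sum over ``steps`` points approximates
    (x - x') * integral_0^1 grad F(x' + a (x - x')) da, and the final map is
    the mean over baselines. The completeness residual
    |sum(attributions) - (F(x) - mean F(x'))| is recorded.
    """
    if steps < 1:
        raise InvalidArgumentError("steps must be >= 1")
    background = list(background)
    if not background:
        raise InvalidArgumentError("background must be non-empty")
    x_ecg, x_meta, pid = _as_arrays(input_sample)
    uses_meta = model._meta_dim > 0
    alphas = (np.arange(steps) + 0.5) / steps

    ecg_attr = np.zeros_like(x_ecg)
    meta_attr = np.zeros_like(x_meta) if (uses_meta and x_meta is not None) else None
    baseline_preds = []
    for item in background:
        b_ecg, b_meta, _ = _as_arrays(item)
        path_ecg = b_ecg[None] + alphas[:, None, None] * (x_ecg - b_ecg)[None]
        if uses_meta:
            path_meta = b_meta[None] + alphas[:, None] * (x_meta - b_meta)[None]
        else:
            path_meta = None
        g_ecg, g_meta, _ = model.input_gradients(path_ecg, path_meta)
        if not np.isfinite(g_ecg).all():
            raise EcgLvhError("non-finite gradients along the integration path")
        ecg_attr += (x_ecg - b_ecg) * g_ecg.mean(axis=0)
        if meta_attr is not None:
            meta_attr += (x_meta - b_meta) * g_meta.mean(axis=0)
        baseline_preds.append(
            float(model.predict_raw(b_ecg[None],
                                    None if not uses_meta else b_meta[None])[0])
        )
    n_bg = len(background)
    ecg_attr /= n_bg
    if meta_attr is not None:
        meta_attr /= n_bg

    prediction = float(model.predict_raw(
        x_ecg[None], None if not uses_meta else x_meta[None])[0])
    baseline_mean = float(np.mean(baseline_preds))
    total = float(ecg_attr.sum() + (meta_attr.sum() if meta_attr is not None else 0.0))
    residual = abs(total - (prediction - baseline_mean))
    return AttributionMap(
        participant_id=pid,
        ecg_attributions=ecg_attr,
        metadata_attributions=meta_attr,
        n_background=n_bg,
        baseline_prediction_mean=baseline_mean,
        prediction=prediction,
        n_path_steps=steps,
        completeness_residual=residual,
    )


def metadata_importance_summary(maps, metadata_values=None):
    """Rank metadata features by mean |attribution| across attribution maps.

    Returns (ranked, beeswarm): ``ranked`` is a DataFrame with one row per
    feature (mean |attribution|, mean signed attribution, rank), ``beeswarm``
    a long-format DataFrame of individual signed attributions, optionally
    joined with the raw feature values for coloring.
    """
    maps = list(maps)
    if not maps:
        raise InvalidArgumentError("need at least one attribution map")
    if maps[0].metadata_attributions is None:
        raise InvalidArgumentError("maps carry no metadata attributions")
    matrix = np.vstack([m.metadata_attributions for m in maps])
    features = list(METADATA_MANIFEST)
    ranked = pd.DataFrame({
        "feature": features,
        "mean_abs_attribution": np.abs(matrix).mean(axis=0),
        "mean_attribution": matrix.mean(axis=0),
    }).sort_values("mean_abs_attribution", ascending=False, kind="stable")
    ranked["rank"] = np.arange(1, len(features) + 1)
    rows = {
        "participant_id": np.repeat([m.participant_id for m in maps], len(features)),
        "feature": np.tile(features, len(maps)),
        "attribution": matrix.ravel(),
    }
    if metadata_values is not None:
        rows["feature_value"] = np.asarray(metadata_values, dtype=float).ravel()
    return ranked.reset_index(drop=True), pd.DataFrame(rows)


def percentile_group_waveforms(
    predictions,
    waveforms,
    lower: float = 5.0,
    upper: float = 95.0,
):
    """Mean +- SD waveforms for the prediction-extreme groups.

    Groups are participants with predictions below the ``lower`` or above the
    ``upper`` empirical percentile. Returns a dict with the two boolean masks
    and per-group (8, L) mean and SD arrays.
    """
    predictions = np.asarray(predictions, dtype=float)
    waveforms = np.asarray(waveforms, dtype=float)
    if predictions.size < 20:
        raise InvalidArgumentError("need at least 20 participants for percentile groups")
    if waveforms.shape[0] != predictions.size:
        raise InvalidArgumentError("one waveform per prediction required")
    lo_val = np.percentile(predictions, lower)
    hi_val = np.percentile(predictions, upper)
    low_mask = predictions < lo_val
    high_mask = predictions > hi_val
    if not low_mask.any() or not high_mask.any():
        raise GroupingError(
            "degenerate percentile grouping (constant or near-constant predictions)"
        )
    return {
        "low_mask": low_mask,
        "high_mask": high_mask,
        "low_mean": waveforms[low_mask].mean(axis=0),
        "low_sd": waveforms[low_mask].std(axis=0),
        "high_mean": waveforms[high_mask].mean(axis=0),
        "high_sd": waveforms[high_mask].std(axis=0),
    }
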