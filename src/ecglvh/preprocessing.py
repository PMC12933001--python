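"""ECG preprocessing: from raw recordings to model-ready feature vectors.

The median heartbeat is computed by the classical signal-averaging recipe:
band-pass Butterworth filtering (1-45 Hz, zero phase), R-wave detection on the
first principal component of the eight leads, beat alignment by time-lagged
normalized cross-correlation with rejection of uncorrelated beats, and
pointwise averaging of the retained beats. The mean R-R interval (ventricular
rate) is the only ECG-derived biomarker carried into the clinical metadata.

Continuous metadata features are min-max normalized relative to the training
partition; smoking status is one-hot encoded; binary variables pass through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sst

from .clinical import ClinicalProfile, SMOKING_LEVELS, profiles_to_frame
from .core import REQUIRED_LEADS, MedianBeat, RawEcg
from .errors import (
    DegenerateFeatureError,
    ExtractionError,
    ImputationError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

#: All signal processing happens at this rate; other inputs are resampled.
PROCESSING_RATE_HZ = 500.0

#: Median-beat window around the R peak: 400 ms before, 800 ms after (1.2 s).
BEAT_WINDOW_S = (-0.4, 0.8)

#: Default normalized-cross-correlation threshold for beat retention.
CORRELATION_THRESHOLD = 0.8

#: Alignment search range around the detected R peak.
MAX_LAG_MS = 50.0

#: Refractory period for R-peak detection.
REFRACTORY_MS = 250.0


# ---------------------------------------------------------------------------
# filtering and peak detection

def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 1.0, high: float = 45.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length.

    Applied forward-backward (sosfiltfilt), so the effective magnitude
    response is squared and phase distortion is zero — QRS timing is
    preserved.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high:
        raise InvalidArgumentError(f"fs={fs} must exceed twice the upper edge {high}")
    if x.shape[-1] <= 3 * order:
        raise InvalidArgumentError("signal too short for the filter order")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def resample_to(ecg: RawEcg, fs_out: float = PROCESSING_RATE_HZ) -> RawEcg:
    """Linearly resample a recording to ``fs_out`` (identity if already there)."""
    if abs(ecg.sampling_rate_hz - fs_out) < 1e-9:
        return ecg
    n_in = ecg.samples.shape[1]
    n_out = round(ecg.duration_s * fs_out)
    t_in = np.arange(n_in) / ecg.sampling_rate_hz
    t_out = np.arange(n_out) / fs_out
    resampled = np.vstack([np.interp(t_out, t_in, lead) for lead in ecg.samples])
    return RawEcg(
        participant_id=ecg.participant_id,
        lead_names=ecg.lead_names,
        samples=resampled,
        sampling_rate_hz=fs_out,
        duration_s=n_out / fs_out,
    )


def _first_principal_component(filtered: np.ndarray) -> np.ndarray:
    """Score of the first PC across leads (time series, arbitrary sign)."""
    centred = filtered - filtered.mean(axis=1, keepdims=True)
    # SVD of (n_samples, n_leads); first left singular vector * singular value
    u, s, _ = np.linalg.svd(centred.T, full_matrices=False)
    return u[:, 0] * s[0]


def detect_r_peaks(ecg: RawEcg, prefiltered: np.ndarray | None = None) -> np.ndarray:
    """R-peak sample indices from the first principal component of the leads.

    The principal component is band-passed to the QRS energy band (8-25 Hz,
    suppressing P and T waves) and rectified; candidate peaks must exceed an
    adaptive threshold of 0.5 x the 95th percentile of the rectified signal
    (computed over ~2 s chunks) and respect a 250 ms refractory period. Each
    candidate is then refined to the extremum of the broadband component
    within +-40 ms. Sign-invariant by construction.
    """
    if ecg.duration_s < 3.0:
        raise InvalidArgumentError("need at least 3 s of signal for peak detection")
    fs = ecg.sampling_rate_hz
    filtered = (
        prefiltered
        if prefiltered is not None
        else bandpass_filter(ecg.in_canonical_order(), fs)
    )
    pc = _first_principal_component(filtered)
    if not pc.any():
        logger.warning("%s: flat signal, no peaks found", ecg.participant_id)
        return np.array([], dtype=int)
    qrs = np.abs(bandpass_filter(pc, fs, low=8.0, high=25.0, order=2))

    chunk = max(round(2.0 * fs), 1)
    n_chunks = int(np.ceil(qrs.size / chunk))
    thresholds = np.empty_like(qrs)
    for c in range(n_chunks):
        sl = slice(c * chunk, min((c + 1) * chunk, qrs.size))
        thresholds[sl] = np.percentile(qrs[sl], 95)
    peaks, _ = sps.find_peaks(
        qrs, height=0.5 * thresholds, distance=max(round(REFRACTORY_MS / 1000 * fs), 1)
    )
    if peaks.size == 0:
        logger.warning("%s: no R peaks found", ecg.participant_id)
        return peaks.astype(int)
    # refine to the broadband extremum near each candidate
    half = round(0.04 * fs)
    abs_pc = np.abs(pc)
    refined = [
        max(p - half, 0) + int(np.argmax(abs_pc[max(p - half, 0) : p + half + 1]))
        for p in peaks
    ]
    refined = np.unique(refined)
    # re-impose the refractory period after refinement
    out = []
    for p in refined:
        if not out or p - out[-1] >= round(REFRACTORY_MS / 1000 * fs):
            out.append(int(p))
        elif abs_pc[p] > abs_pc[out[-1]]:
            out[-1] = int(p)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# median-beat extraction

def _beat_windows(filtered, peaks, pre, length, lags):
    """(n_beats, n_lags, 8*L) matrix of flattened candidate windows."""
    n_samples = filtered.shape[1]
    keep = [
        p for p in peaks
        if p - pre + lags.min() >= 0 and p - pre + lags.max() + length <= n_samples
    ]
    windows = np.empty((len(keep), lags.size, filtered.shape[0] * length))
    base = np.arange(length)
    for bi, p in enumerate(keep):
        idx = (p - pre) + lags[:, None] + base[None, :]  # (n_lags, L)
        windows[bi] = filtered[:, idx].transpose(1, 0, 2).reshape(lags.size, -1)
    return np.asarray(keep, dtype=int), windows


def extract_median_beat(
    ecg: RawEcg,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    max_lag_ms: float = MAX_LAG_MS,
) -> MedianBeat:
    """Signal-averaged beat per lead, with beat rejection and rate derivation.

    Each detected beat is windowed over [-400 ms, +800 ms) around its R peak,
    aligned to a robust template (pointwise median across all candidate
    windows) by the lag in +-``max_lag_ms`` maximizing normalized
    cross-correlation over the concatenated leads, and rejected when that
    maximal correlation falls below ``correlation_threshold``. Retained
    aligned beats are combined by a pointwise trimmed mean. The mean R-R interval is taken over
    consecutive retained beats.
    """
    ecg = resample_to(ecg)
    fs = ecg.sampling_rate_hz
    filtered = bandpass_filter(ecg.in_canonical_order(), fs)
    peaks = detect_r_peaks(ecg, prefiltered=filtered)
    if peaks.size < 3:
        raise ExtractionError(
            f"{ecg.participant_id}: only {peaks.size} beats detected",
            participant_id=ecg.participant_id,
        )
    pre = round(-BEAT_WINDOW_S[0] * fs)
    length = round((BEAT_WINDOW_S[1] - BEAT_WINDOW_S[0]) * fs)
    max_lag = round(max_lag_ms / 1000.0 * fs)
    lags = np.arange(-max_lag, max_lag + 1)

    kept_peaks, windows = _beat_windows(filtered, peaks, pre, length, lags)
    if kept_peaks.size < 3:
        raise ExtractionError(
            f"{ecg.participant_id}: fewer than 3 complete beat windows",
            participant_id=ecg.participant_id,
        )
    zero_lag = max_lag  # index of lag 0
    template = np.median(windows[:, zero_lag, :], axis=0)

    t_c = template - template.mean()
    t_norm = np.linalg.norm(t_c)
    # Pearson correlation without materializing centred copies: the template
    # is centred, so windows @ t_c already equals the centred cross product.
    n_pts = windows.shape[2]
    w_sum = windows.sum(axis=2)
    w_sq = np.einsum("blk,blk->bl", windows, windows)
    w_norm = np.sqrt(np.maximum(w_sq - w_sum**2 / n_pts, 0.0))
    denom = np.where(w_norm * t_norm > 0, w_norm * t_norm, np.inf)
    corr = (windows @ t_c) / denom  # (n_beats, n_lags)
    best_lag_idx = corr.argmax(axis=1)
    best_corr = corr[np.arange(corr.shape[0]), best_lag_idx]

    retained = best_corr >= correlation_threshold
    if retained.sum() < 3:
        raise ExtractionError(
            f"{ecg.participant_id}: only {int(retained.sum())} beats retained",
            participant_id=ecg.participant_id,
        )
    aligned = windows[np.arange(windows.shape[0]), best_lag_idx, :]
    # pointwise trimmed mean over retained beats: near-mean noise efficiency,
    # but robust to artefact-beat tails leaking into neighbouring windows
    kept = aligned[retained]
    if kept.shape[0] >= 5:
        averaged = sst.trim_mean(kept, 0.25, axis=0)
    else:
        averaged = kept.mean(axis=0)
    averaged = averaged.reshape(len(REQUIRED_LEADS), length)

    # mean R-R over consecutive retained beats (aligned peak positions)
    adj_peaks = kept_peaks + lags[best_lag_idx]
    retained_idx = np.flatnonzero(retained)
    consecutive = np.diff(retained_idx) == 1
    if consecutive.any():
        rr_samples = np.diff(adj_peaks[retained_idx])[consecutive]
    else:  # fall back to all detected peaks
        rr_samples = np.diff(peaks)
    mean_rr_ms = float(rr_samples.mean() / fs * 1000.0)

    return MedianBeat(
        participant_id=ecg.participant_id,
        waveforms=averaged,
        sampling_rate_hz=fs,
        mean_rr_ms=mean_rr_ms,
        n_beats_detected=int(peaks.size),
        n_beats_retained=int(retained.sum()),
        r_sample=pre,
        retained_peak_indices=tuple(int(p) for p in adj_peaks[retained_idx]),
    )


def decimate_waveform(
    waveform: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Integer-factor decimation of an already band-limited beat.

    The median beat is band-limited to 45 Hz by the preprocessing filter, so
    plain sample picking is alias-free for any output rate above 90 Hz.
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidArgumentError(
            f"fs_in/fs_out must be an integer factor, got {fs_in}/{fs_out}"
        )
    if fs_out <= 90.0:
        raise InvalidArgumentError("output rate must exceed 90 Hz (2 x 45 Hz band edge)")
    return np.ascontiguousarray(waveform[..., :: int(round(factor))])


# ---------------------------------------------------------------------------
# metadata normalization and assembly

CONTINUOUS_FEATURES = (
    "age", "bmi", "sbp_adj", "dbp_adj", "total_chol_adj", "non_hdl_adj",
    "ventricular_rate_bpm",
)
BINARY_FEATURES = ("sex", "hypertension", "diabetes", "hypercholesterolaemia",
                   "alcohol")

#: Fixed 15-entry metadata manifest (order of the model's metadata vector).
METADATA_MANIFEST = (
    "age", "sex", "bmi", "sbp_adj", "dbp_adj", "hypertension", "diabetes",
    "hypercholesterolaemia", "total_chol_adj", "non_hdl_adj", "alcohol",
    "smoking_never", "smoking_previous", "smoking_current",
    "ventricular_rate_bpm",
)


@dataclass(frozen=True)
class NormalizationStats:
    """Training-partition min/max per continuous feature + feature manifest."""

    minima: dict
    maxima: dict
    manifest: tuple = METADATA_MANIFEST

    def normalize(self, feature: str, value):
        lo, hi = self.minima[feature], self.maxima[feature]
        return (np.asarray(value, dtype=float) - lo) / (hi - lo)

    def denormalize(self, feature: str, value):
        lo, hi = self.minima[feature], self.maxima[feature]
        return np.asarray(value, dtype=float) * (hi - lo) + lo


@dataclass
class FeatureVector:
    """Model input: 8 x L beat waveform (mV) + fixed-order metadata vector."""

    participant_id: str
    ecg: np.ndarray
    metadata: np.ndarray

    def __post_init__(self):
        self.metadata = np.asarray(self.metadata, dtype=float)
        if self.metadata.shape != (len(METADATA_MANIFEST),):
            raise InvalidArgumentError(
                f"metadata must have {len(METADATA_MANIFEST)} entries"
            )


def _profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(list(profiles))


def fit_normalization(profiles) -> NormalizationStats:
    """Per-feature min/max from the training partition only.

    ``profiles`` are prepared clinical profiles (adjusted fields and
    ventricular rate filled) or an equivalent DataFrame.
    """
    frame = _profile_frame(profiles)
    if len(frame) == 0:
        raise InvalidArgumentError("training set is empty")
    minima, maxima = {}, {}
    for feature in CONTINUOUS_FEATURES:
        values = frame[feature].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise InvalidArgumentError(f"{feature} contains missing values; impute first")
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            raise DegenerateFeatureError(f"feature {feature!r} is constant ({lo})")
        minima[feature], maxima[feature] = lo, hi
    return NormalizationStats(minima=minima, maxima=maxima)


def smoking_one_hot(status: str) -> np.ndarray:
    if status not in SMOKING_LEVELS:
        raise InvalidArgumentError(f"unknown smoking status {status!r}")
    return (np.asarray(SMOKING_LEVELS) == status).astype(float)


def metadata_vector(profile: ClinicalProfile, stats: NormalizationStats) -> np.ndarray:
    """Assemble the 15-entry metadata vector in manifest order."""
    if profile.ventricular_rate_bpm is None or profile.hypertension is None:
        raise InvalidArgumentError(
            f"{profile.participant_id}: profile incomplete (rate or derived flags missing)"
        )
    one_hot = smoking_one_hot(profile.smoking)
    values = {
        "age": stats.normalize("age", profile.age),
        "sex": float(profile.sex),
        "bmi": stats.normalize("bmi", profile.bmi),
        "sbp_adj": stats.normalize("sbp_adj", profile.sbp_adj),
        "dbp_adj": stats.normalize("dbp_adj", profile.dbp_adj),
        "hypertension": float(profile.hypertension),
        "diabetes": float(profile.diabetes),
        "hypercholesterolaemia": float(profile.hypercholesterolaemia),
        "total_chol_adj": stats.normalize("total_chol_adj", profile.total_chol_adj),
        "non_hdl_adj": stats.normalize("non_hdl_adj", profile.non_hdl_adj),
        "alcohol": float(profile.alcohol),
        "smoking_never": one_hot[0],
        "smoking_previous": one_hot[1],
        "smoking_current": one_hot[2],
        "ventricular_rate_bpm": stats.normalize(
            "ventricular_rate_bpm", profile.ventricular_rate_bpm
        ),
    }
    return np.array([values[name] for name in stats.manifest], dtype=float)


def build_feature_vector(
    beat: MedianBeat | np.ndarray,
    profile: ClinicalProfile,
    stats: NormalizationStats,
) -> FeatureVector:
    """Waveform (passed through unchanged, in mV) + normalized metadata."""
    waveform = beat.waveforms if isinstance(beat, MedianBeat) else np.asarray(beat)
    return FeatureVector(
        participant_id=profile.participant_id,
        ecg=waveform,
        metadata=metadata_vector(profile, stats),
    )


# ---------------------------------------------------------------------------
# imputation

def impute_missing(profiles):
    """Mode imputation for binary/categorical columns, median for continuous.

    Accepts and returns a DataFrame (or a list of ClinicalProfile, converted
    through the tabular schema). Statistics are computed over the non-missing
    values of the same input collection.
    """
    from .clinical import frame_to_profiles

    as_frame = isinstance(profiles, pd.DataFrame)
    frame = (_profile_frame(profiles)).copy()
    for column in frame.columns:
        missing = frame[column].isna()
        if not missing.any():
            continue
        observed = frame.loc[~missing, column]
        if len(observed) == 0:
            raise ImputationError(f"column {column!r} is entirely missing")
        numeric = pd.api.types.is_numeric_dtype(observed) and not (
            pd.api.types.is_bool_dtype(observed)
        )
        is_binary = numeric and set(pd.unique(observed)) <= {0, 1, 0.0, 1.0}
        if numeric and not is_binary:
            fill = observed.median()
        else:
            fill = observed.mode(dropna=True).iloc[0]
        frame.loc[missing, column] = fill
    return frame if as_frame else frame_to_profiles(frame)
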