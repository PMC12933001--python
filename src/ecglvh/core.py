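"""Core waveform containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Canonical order of the eight independent leads used throughout.
REQUIRED_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Aliases mapped onto canonical lead names (case-insensitive).
LEAD_ALIASES = {
    "i": "I", "lead i": "I", "mdc_ecg_lead_i": "I",
    "ii": "II", "lead ii": "II", "mdc_ecg_lead_ii": "II",
    **{f"v{k}": f"V{k}" for k in range(1, 7)},
    **{f"c{k}": f"V{k}" for k in range(1, 7)},
    **{f"lead v{k}": f"V{k}" for k in range(1, 7)},
}


def canonical_lead(name: str) -> str | None:
    """Map a lead label (or alias such as ``C1``) to its canonical name."""
    key = name.strip().lower()
    if key in LEAD_ALIASES:
        return LEAD_ALIASES[key]
    return None


@dataclass
class RawEcg:
    """A multi-lead raw ECG recording in millivolts.

    ``samples`` has shape (n_leads, n_samples) ordered as ``lead_names``.
    """

    participant_id: str
    lead_names: tuple[str, ...]
    samples: np.ndarray
    sampling_rate_hz: float
    duration_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.lead_names):
            raise InvalidArgumentError("samples must be (n_leads, n_samples)")
        expected = round(self.duration_s * self.sampling_rate_hz)
        if self.samples.shape[1] != expected:
            raise InvalidArgumentError(
                f"length {self.samples.shape[1]} != duration*fs ({expected})"
            )
        missing = [l for l in REQUIRED_LEADS if l not in self.lead_names]
        if missing:
            raise InvalidArgumentError(f"missing required leads: {missing}")

    def lead(self, name: str) -> np.ndarray:
        return self.samples[self.lead_names.index(name)]

    def in_canonical_order(self) -> np.ndarray:
        """Return the 8 required leads as an (8, n_samples) array."""
        idx = [self.lead_names.index(l) for l in REQUIRED_LEADS]
        return self.samples[idx]


@dataclass
class MedianBeat:
    """Per-lead signal-averaged beat plus rate and retention bookkeeping."""

    participant_id: str
    waveforms: np.ndarray  # (8, L) in mV, canonical lead order
    sampling_rate_hz: float
    mean_rr_ms: float
    n_beats_detected: int
    n_beats_retained: int
    r_sample: int  # index of the alignment (R) point within the window
    retained_peak_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 2 or self.waveforms.shape[0] != len(REQUIRED_LEADS):
            raise InvalidArgumentError("waveforms must be (8, L)")
        if self.n_beats_retained > self.n_beats_detected:
            raise InvalidArgumentError("retained beats cannot exceed detected beats")
        if self.mean_rr_ms <= 0:
            raise InvalidArgumentError("mean_rr_ms must be positive")

    @property
    def ventricular_rate_bpm(self) -> float:
        return 60000.0 / self.mean_rr_ms

    def lead(self, name: str) -> np.ndarray:
        return self.waveforms[REQUIRED_LEADS.index(name)]
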