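"""Reading and writing ECG recordings.

Two interchange formats are supported:

* a plain columnar text format (one column per lead, ``#``-prefixed header
  carrying participant id, sampling rate and units) — the package's native
  text format, safe for version control;
* EDF (European Data Format). Reading goes through MNE; writing uses a
  minimal self-contained EDF writer (ASCII header + 16-bit integer records)
  because no EDF-writing library is bundled with the package's dependencies.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np

from .core import REQUIRED_LEADS, RawEcg, canonical_lead
from .errors import FormatError, UnitError

logger = logging.getLogger(__name__)

_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3}


# ---------------------------------------------------------------------------
# columnar text format

def write_text_ecg(ecg: RawEcg, path) -> None:
    path = Path(path)
    header = (
        f"# participant_id: {ecg.participant_id}\n"
        f"# sampling_rate_hz: {ecg.sampling_rate_hz}\n"
        f"# units: mV\n"
        f"# leads: {' '.join(ecg.lead_names)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ecg.samples.T, fmt="%.6f")


def read_text_ecg(path) -> RawEcg:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            data_start = i + 1
        else:
            break
    if "leads" not in meta or "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: missing '# leads:' or '# sampling_rate_hz:' header")
    samples = np.loadtxt(lines[data_start:], ndmin=2).T
    unit = meta.get("units", "mV").lower()
    if unit not in _UNIT_TO_MV:
        raise UnitError(f"{path}: cannot convert unit {unit!r} to mV")
    samples = samples * _UNIT_TO_MV[unit]
    lead_names, keep = _canonicalize(meta["leads"].split())
    fs = float(meta["sampling_rate_hz"])
    return RawEcg(
        participant_id=meta.get("participant_id", path.stem),
        lead_names=lead_names,
        samples=samples[keep],
        sampling_rate_hz=fs,
        duration_s=samples.shape[1] / fs,
    )


def _canonicalize(names: list[str]) -> tuple[tuple[str, ...], list[int]]:
    """Map labels to canonical lead names; check the 8 required leads exist."""
    mapped, keep = [], []
    for i, n in enumerate(names):
        canon = canonical_lead(n)
        if canon is not None and canon not in mapped:
            mapped.append(canon)
            keep.append(i)
    missing = [l for l in REQUIRED_LEADS if l not in mapped]
    if missing:
        raise FormatError(f"missing required leads: {missing}")
    return tuple(mapped), keep


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_edf(ecg: RawEcg, path) -> None:
    """Write an EDF file with one channel per lead, physical units mV.

    The recording is chunked into one-second data records; a trailing partial
    second is zero-padded. Amplitude resolution is the physical range of each
    lead mapped onto the 16-bit digital range, i.e. quantization error is
    (max-min)/65535 mV.
    """
    path = Path(path)
    fs = ecg.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(ecg.lead_names)
    n_records = int(np.ceil(ecg.samples.shape[1] / fs))
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, : ecg.samples.shape[1]] = ecg.samples

    phys_min = np.floor(padded.min(axis=1) * 1000) / 1000 - 1e-3
    phys_max = np.ceil(padded.max(axis=1) * 1000) / 1000 + 1e-3
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint(
        (padded - phys_min[:, None]) * gain[:, None] + dig_min
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(ecg.participant_id, 80),
        _edf_field("ecglvh synthetic recording", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_sig, 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(name, 16) for name in ecg.lead_names),
        b"".join(_edf_field("", 80) for _ in range(n_sig)),
        b"".join(_edf_field("mV", 8) for _ in range(n_sig)),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(_edf_field(dig_min, 8) for _ in range(n_sig)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 80) for _ in range(n_sig)),
        b"".join(_edf_field(fs, 8) for _ in range(n_sig)),
        b"".join(_edf_field("", 32) for _ in range(n_sig)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path, participant_id: str | None = None) -> RawEcg:
    """Read an EDF recording via MNE and convert to millivolts."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    # MNE rescales recognised channels to SI units (volts).
    data_mv = raw.get_data() * 1e3
    lead_names, keep = _canonicalize(list(raw.ch_names))
    fs = float(raw.info["sfreq"])
    data_mv = data_mv[keep]
    return RawEcg(
        participant_id=participant_id or path.stem,
        lead_names=lead_names,
        samples=data_mv,
        sampling_rate_hz=fs,
        duration_s=data_mv.shape[1] / fs,
    )


def read_ecg(path, format: str | None = None, participant_id: str | None = None) -> RawEcg:
    """Read an ECG recording, auto-detecting the format from the suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text"
    if format == "edf":
        return read_edf(path, participant_id=participant_id)
    if format == "text":
        ecg = read_text_ecg(path)
        if participant_id is not None:
            ecg.participant_id = participant_id
        return ecg
    raise FormatError(f"unknown ECG format {format!r}")
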