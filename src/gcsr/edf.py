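"""Minimal European Data Format (EDF) writer plus an MNE-backed reader.

Only the subset of EDF needed for this pipeline is implemented on the write
side: one continuous recording, a common sampling rate, 16-bit samples with
per-channel physical scaling, 1 s data records.  Reading goes through
``mne.io.read_raw_edf`` so round-trips are checked against an independent
implementation of the format.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    channels: tuple[str, ...] | list[str],
    fs: float,
    physical_unit: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> Path:
    """Write channels x samples data (physical units) as EDF.

    The record duration is 1 s, so ``fs`` must be an integer sample count per
    second.  The final partial record, if any, is zero-padded; NaNs are
    stored as zeros (callers keep rejection masks separately).
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(channels):
        raise ValueError("data must be channels x samples matching the channel list")
    if fs != int(fs):
        raise ValueError("fs must be an integer number of samples per second")
    spr = int(fs)  # samples per record per channel
    n_ch, n_samples = data.shape
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = np.nan_to_num(data, nan=0.0)

    phys_min = np.floor(np.nanmin(padded, axis=1))
    phys_max = np.ceil(np.nanmax(padded, axis=1))
    # avoid zero span on flat channels
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_field(ch, 16) for ch in channels),
            b"".join(_field("", 80) for _ in channels),
            b"".join(_field(physical_unit, 8) for _ in channels),
            b"".join(_field(f"{phys_min[c]:.0f}", 8) for c in range(n_ch)),
            b"".join(_field(f"{phys_max[c]:.0f}", 8) for c in range(n_ch)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in channels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in channels),
            b"".join(_field("", 80) for _ in channels),
            b"".join(_field(str(spr), 8) for _ in channels),
            b"".join(_field("", 32) for _ in channels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        # record-interleaved: for each record, each channel's spr samples
        interleaved = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved).tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Read an EDF file back as (channels x samples in uV, channel names, fs)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return data, tuple(raw.ch_names), float(raw.info["sfreq"])
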