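"""Goal-conflict-specific rhythmicity (GCSR) extraction.

The biomarker is a within-participant spectral contrast computed from 1 s
epochs around each stop signal:

* a *stop* epoch starts 0.25 s before the stop signal, so the Hanning taper
  concentrates sensitivity on the 0.5 s during which stopping and going
  compete;
* a *matched go* epoch takes the same window geometry from the immediately
  adjacent go trial — placed at that go trial's arrow onset plus the stop
  trial's SSD, minus 0.25 s — so go epochs sample the same post-stimulus
  latency without a stop signal;
* each epoch is Hanning-tapered, Fourier transformed, converted to power at
  the 1 Hz bins 4..12 Hz and log transformed (log first, then averaged over
  trials, to normalize error variance);
* per participant, block and channel, the Stop-Go log-power difference D is
  formed at each SSD level, and

      GCSR(f) = D_medium(f) - (D_short(f) + D_long(f)) / 2

  i.e. the quadratic SSD contrast of the stop-specific power: positive
  values mean excess rhythmicity when stopping and going are in balanced
  conflict relative to when one of them dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EPOCH_SAMPLES",
    "FREQ_BINS_HZ",
    "EpochWindow",
    "locate_epochs",
    "hann_log_power",
    "extract_epoch_spectra",
    "average_cells",
    "gcsr",
    "participant_gcsr",
]

FS = 128.0
PRE_STOP_S = 0.25
WINDOW_S = 1.0
EPOCH_SAMPLES = int(WINDOW_S * FS)  # 128 -> 1 Hz frequency resolution
FREQ_BINS_HZ = tuple(range(4, 13))
LOG_FLOOR = 1e-12  # power floor before the log, in uV^2 units

CELL_KEYS = ["block", "channel", "trial_type", "ssd_level"]


@dataclass(frozen=True)
class EpochWindow:
    """One analysis window tied back to the stop trial that defines it."""

    trial_index: int  # the stop trial anchoring this window
    source_index: int  # trial the data come from (== trial_index for stop epochs)
    block: int
    trial_type: str  # "stop" | "go"
    ssd_level: str  # "short" | "medium" | "long"
    start_s: float


def locate_epochs(trials: pd.DataFrame, record_duration_s: float) -> tuple[list[EpochWindow], list[str]]:
    """Pair each stop trial with a matched go window.

    ``trials`` is the per-trial behavioural table (columns block, kind,
    staircase, arrow_onset_s, stop_onset_s, ssd_ms).  The matched go trial is
    the nearest preceding go trial; if a stop trial has none in its block the
    nearest following go trial is used.  Stop trials whose stop or matched
    window would run outside the recorded data are dropped and logged.

    Returns the epoch list and a log of exclusions.
    """
    log: list[str] = []
    epochs: list[EpochWindow] = []
    for block, chunk in trials.groupby("block", sort=True):
        chunk = chunk.sort_values("index")
        go = chunk[chunk["kind"] == "go"]
        for _, stop in chunk[chunk["kind"] == "stop"].iterrows():
            ssd_s = stop["ssd_ms"] / 1000.0
            stop_start = stop["stop_onset_s"] - PRE_STOP_S
            preceding = go[go["index"] < stop["index"]]
            if len(preceding):
                match = preceding.iloc[-1]
            else:
                following = go[go["index"] > stop["index"]]
                if not len(following):
                    log.append(f"trial {int(stop['index'])}: no eligible matched go trial")
                    continue
                match = following.iloc[0]
            go_start = match["arrow_onset_s"] + ssd_s - PRE_STOP_S
            if not (
                0.0 <= stop_start
                and stop_start + WINDOW_S <= record_duration_s
                and 0.0 <= go_start
                and go_start + WINDOW_S <= record_duration_s
            ):
                log.append(f"trial {int(stop['index'])}: window outside record bounds")
                continue
            common = dict(
                trial_index=int(stop["index"]),
                block=int(block),
                ssd_level=stop["staircase"],
            )
            epochs.append(
                EpochWindow(source_index=int(stop["index"]), trial_type="stop",
                            start_s=float(stop_start), **common)
            )
            epochs.append(
                EpochWindow(source_index=int(match["index"]), trial_type="go",
                            start_s=float(go_start), **common)
            )
    return epochs, log


def hann_log_power(epoch: np.ndarray) -> np.ndarray:
    """Hanning-tapered log Fourier power at the 4..12 Hz bins.

    Accepts a single 128-sample epoch or a batch (..., 128).  Power at bin f
    is |X(f)|^2 * 2 / N^2 (one-sided convention; the constant cancels in all
    the contrasts but is fixed for reproducibility), floored at 1e-12 before
    the natural log.  Epochs containing missing samples return NaN across all
    bins, signalling upstream exclusion.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-1] != EPOCH_SAMPLES:
        raise ValueError(f"epoch must have exactly {EPOCH_SAMPLES} samples")
    taper = np.hanning(EPOCH_SAMPLES)
    spec = np.fft.rfft(epoch * taper, axis=-1)
    power = (np.abs(spec) ** 2) * 2.0 / EPOCH_SAMPLES**2
    out = np.log(np.maximum(power[..., FREQ_BINS_HZ[0] : FREQ_BINS_HZ[-1] + 1], LOG_FLOOR))
    bad = ~np.all(np.isfinite(epoch), axis=-1)
    if np.ndim(bad) == 0:
        if bad:
            out = np.full(len(FREQ_BINS_HZ), np.nan)
    else:
        out[bad] = np.nan
    return out


def extract_epoch_spectra(
    data: np.ndarray,
    channels: tuple[str, ...],
    fs: float,
    epochs: list[EpochWindow],
    analysis_channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Log-power spectra for every epoch x analysis channel, tidy long form.

    Epochs with any missing (NaN) sample on a channel yield NaN spectra on
    that channel and are dropped from the returned table (their exclusion is
    visible through n_trials downstream).
    """
    if fs != FS:
        raise ValueError(f"analysis assumes {FS} Hz sampling, got {fs}")
    analysis_channels = analysis_channels or tuple(c for c in channels if c != "Fp1")
    ch_idx = {c: channels.index(c) for c in analysis_channels}
    rows = []
    for ep in epochs:
        i0 = int(round(ep.start_s * fs))
        for ch, ci in ch_idx.items():
            segment = data[ci, i0 : i0 + EPOCH_SAMPLES]
            if segment.size != EPOCH_SAMPLES:
                continue
            logp = hann_log_power(segment)
            if not np.all(np.isfinite(logp)):
                continue
            for f, v in zip(FREQ_BINS_HZ, logp):
                rows.append(
                    dict(
                        trial_index=ep.trial_index,
                        block=ep.block,
                        channel=ch,
                        trial_type=ep.trial_type,
                        ssd_level=ep.ssd_level,
                        frequency_hz=f,
                        log_power=v,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_index", "block", "channel", "trial_type",
            "ssd_level", "frequency_hz", "log_power",
        ],
    )


def average_cells(spectra: pd.DataFrame) -> pd.DataFrame:
    """Mean log power per (block, channel, trial_type, ssd_level, frequency).

    Cells with no surviving epochs are absent from the table (missingness is
    explicit downstream: the conflict contrast is undefined, not zero, when a
    contributing cell is empty).
    """
    if spectra.empty:
        return pd.DataFrame(
            columns=CELL_KEYS + ["frequency_hz", "log_power", "n_trials"]
        )
    grouped = (
        spectra.groupby(CELL_KEYS + ["frequency_hz"], sort=True)["log_power"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "log_power", "count": "n_trials"})
    )
    return grouped


def gcsr(cells: pd.DataFrame) -> pd.DataFrame:
    """Conflict contrast per (block, channel, frequency).

    GCSR(f) = D_medium - (D_short + D_long)/2 with D = Stop - Go log power,
    i.e. the quadratic contrast of SSD applied to the stop-specific power,
    with weights (-1/2, 1, -1/2) so one unit equals one log-power unit of
    conflict-specific excess.  Rows are emitted only where all six
    contributing cells exist.
    """
    if cells.empty:
        return pd.DataFrame(columns=["block", "channel", "frequency_hz", "gcsr"])
    wide = cells.pivot_table(
        index=["block", "channel", "frequency_hz"],
        columns=["trial_type", "ssd_level"],
        values="log_power",
        aggfunc="first",
    )
    needed = [(tt, lvl) for tt in ("stop", "go") for lvl in ("short", "medium", "long")]
    if any(col not in wide.columns for col in needed):
        missing_ok = wide.reindex(columns=pd.MultiIndex.from_tuples(needed))
        wide = missing_ok
    d = {lvl: wide[("stop", lvl)] - wide[("go", lvl)] for lvl in ("short", "medium", "long")}
    value = d["medium"] - (d["short"] + d["long"]) / 2.0
    out = value.rename("gcsr").reset_index().dropna(subset=["gcsr"])
    return out.reset_index(drop=True)


def participant_gcsr(
    data: np.ndarray,
    channels: tuple[str, ...],
    fs: float,
    trials: pd.DataFrame,
    analysis_channels: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Full single-participant path: epochs -> spectra -> cells -> GCSR.

    Returns (gcsr table, cell table, exclusion log).
    """
    duration_s = data.shape[1] / fs
    epochs, log = locate_epochs(trials, duration_s)
    spectra = extract_epoch_spectra(data, channels, fs, epochs, analysis_channels)
    cells = average_cells(spectra)
    return gcsr(cells), cells, log
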