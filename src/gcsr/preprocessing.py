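"""EEG cleaning: residual-mains smoothing, blink-template subtraction,
amplitude-based artifact rejection.

The cleaning chain mirrors the recording-side analysis conventions of the
stop-signal biomarker studies:

1. a three-point running mean suppresses residual 50 Hz mains leakage (first
   spectral null at fs/3 = 42.67 Hz for 128 Hz data, i.e. an effective
   ~43 Hz cut-off);
2. eye blinks are removed by fitting a stereotyped blink template to Fp1 and
   subtracting a least-squares-scaled copy from every channel;
3. remaining large-amplitude artifacts are replaced by missing values (NaN),
   with the rejection mask kept alongside the data so downstream epoching can
   exclude contaminated trials outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BlinkTemplate",
    "CleanedEEG",
    "running_mean_filter",
    "running_mean_response",
    "detect_blinks",
    "build_blink_template",
    "remove_blinks",
    "reject_artifacts",
]


@dataclass(frozen=True)
class BlinkTemplate:
    """Ballistic blink waveform fitted at Fp1; unit positive peak."""

    waveform: np.ndarray
    alignment: int  # peak index within the waveform

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("template must be finite")
        if abs(np.max(w) - 1.0) > 1e-9:
            raise ValueError("template must be peak-normalized to 1")

    @property
    def length(self) -> int:
        return int(np.asarray(self.waveform).size)


@dataclass
class CleanedEEG:
    """Channels x samples signal with NaN missing values and a rejection mask."""

    signal: np.ndarray
    channels: tuple[str, ...]
    fs: float
    rejection_mask: np.ndarray  # boolean, channels x samples
    provenance: list[str] = field(default_factory=list)


def running_mean_filter(x: np.ndarray) -> np.ndarray:
    """Three-point running mean, y[n] = (x[n-1] + x[n] + x[n+1]) / 3.

    Endpoints use edge replication.  At 128 Hz the first null of the
    frequency response (1 + 2 cos(2 pi f / fs)) / 3 falls at fs/3 ~ 43 Hz,
    so the filter acts as a gentle low-pass that notches residual mains
    leakage aliased/filtered into the recording band.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    padded = np.concatenate(
        [x[..., :1], x, x[..., -1:]], axis=-1
    )
    return (padded[..., :-2] + padded[..., 1:-1] + padded[..., 2:]) / 3.0


def running_mean_response(f_hz: np.ndarray | float, fs: float = 128.0) -> np.ndarray:
    """Closed-form magnitude response of the 3-point running mean."""
    return np.abs((1.0 + 2.0 * np.cos(2.0 * np.pi * np.asarray(f_hz) / fs)) / 3.0)


def detect_blinks(
    fp1: np.ndarray,
    fs: float,
    threshold_uv: float = 50.0,
    template_len_s: float = 0.3,
    pre_peak_s: float = 0.1,
) -> list[tuple[int, int]]:
    """Threshold-plus-shape blink detector on the Fp1 channel.

    Finds positive peaks exceeding ``threshold_uv`` separated by at least
    half a template length, and returns (start, stop) sample windows of
    ``template_len_s`` around each peak.  Overlapping windows are merged.
    """
    fp1 = np.asarray(fp1, dtype=float)
    n_tmpl = int(round(template_len_s * fs))
    pre = int(round(pre_peak_s * fs))
    peaks, _ = find_peaks(fp1, height=threshold_uv, distance=max(1, n_tmpl // 2))
    windows: list[tuple[int, int]] = []
    for p in peaks:
        start = max(0, p - pre)
        stop = min(fp1.size, start + n_tmpl)
        if windows and start < windows[-1][1]:
            windows[-1] = (windows[-1][0], stop)  # merge overlap
        else:
            windows.append((start, stop))
    return windows


def build_blink_template(
    fp1: np.ndarray,
    windows: list[tuple[int, int]],
) -> BlinkTemplate:
    """Average detected Fp1 blink segments, peak-aligned and peak-normalized."""
    if not windows:
        raise ValueError("no blink windows to build a template from")
    length = max(stop - start for start, stop in windows)
    segments = []
    peak_offsets = []
    for start, stop in windows:
        seg = np.asarray(fp1[start:stop], dtype=float)
        peak_offsets.append(int(np.argmax(seg)))
        segments.append(seg)
    align = int(round(np.median(peak_offsets)))
    acc = np.zeros(length)
    count = np.zeros(length)
    for seg, off in zip(segments, peak_offsets):
        shift = align - off
        lo = max(0, shift)
        hi = min(length, shift + seg.size)
        acc[lo:hi] += seg[lo - shift : hi - shift]
        count[lo:hi] += 1
    mean = np.where(count > 0, acc / np.maximum(count, 1), 0.0)
    peak = np.max(mean)
    if peak <= 0:
        raise ValueError("degenerate blink template (non-positive peak)")
    return BlinkTemplate(waveform=mean / peak, alignment=align)


def remove_blinks(
    data: np.ndarray,
    channels: tuple[str, ...],
    fs: float,
    template: BlinkTemplate,
    windows: list[tuple[int, int]],
) -> CleanedEEG:
    """Subtract a least-squares-scaled template copy from every channel.

    Per blink window and channel the scale is the closed-form projection
    b* = <ch, t> / <t, t>; subtracting b*.t minimizes the residual squared
    error within the window, so channels orthogonal to the template are left
    untouched and exact template multiples are removed completely.
    """
    data = np.array(data, dtype=float)
    tfull = np.asarray(template.waveform, dtype=float)
    if np.dot(tfull, tfull) == 0:
        raise ValueError("zero-energy template")
    n_samples = data.shape[1]
    for start, stop in windows:
        if start < 0 or stop > n_samples:
            raise ValueError(f"blink window ({start}, {stop}) outside record bounds")
        t = tfull[: stop - start]
        energy = float(np.dot(t, t))
        if energy == 0:
            continue
        seg = data[:, start:stop]
        b = seg @ t / energy  # per-channel scale
        data[:, start:stop] = seg - np.outer(b, t)
    return CleanedEEG(
        signal=data,
        channels=tuple(channels),
        fs=fs,
        rejection_mask=np.zeros(data.shape, dtype=bool),
        provenance=[f"remove_blinks: {len(windows)} windows, template_len={template.length}"],
    )


def reject_artifacts(
    cleaned: CleanedEEG,
    amplitude_threshold_uv: float = 150.0,
    window_pad_s: float = 0.1,
) -> CleanedEEG:
    """Flag samples beyond |threshold| (plus padding) and set them to NaN.

    Automates the manual artifact pass: anything the blink removal left with
    implausible amplitude is replaced by missing values so that epochs
    touching it are excluded rather than averaged in.
    """
    if amplitude_threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    signal = np.array(cleaned.signal, dtype=float)
    pad = int(round(window_pad_s * cleaned.fs))
    with np.errstate(invalid="ignore"):
        bad = np.abs(signal) > amplitude_threshold_uv
    if pad > 0 and bad.any():
        kernel = np.ones(2 * pad + 1)
        for c in range(bad.shape[0]):
            bad[c] = np.convolve(bad[c].astype(float), kernel, mode="same") > 0
    mask = cleaned.rejection_mask | bad | np.isnan(signal)
    signal[mask] = np.nan
    return CleanedEEG(
        signal=signal,
        channels=cleaned.channels,
        fs=cleaned.fs,
        rejection_mask=mask,
        provenance=cleaned.provenance
        + [f"reject_artifacts: threshold={amplitude_threshold_uv}uV pad={window_pad_s}s"],
    )
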