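"""Synthetic cohorts: race-model stop-signal behaviour and continuous EEG.

No raw data accompany the study this package operationalizes, so every
downstream stage is exercised on simulated participants whose behaviour and
electrophysiology reproduce the published summary structure:

* Go reaction times are ex-Gaussian with cohort mean ~425 ms;
* stopping follows the independent horse-race model with a stop process of
  ~240 ms, so the medium staircase tracks the ~50% inhibition point while the
  short and long staircases yield mostly-successful and mostly-failed stops;
* EEG is 128 Hz pink noise plus 50 Hz mains and stereotyped eye blinks,
  band-passed 1-36 Hz, on channels Fp1, F7, F3, Fz, F4, F8;
* a goal-conflict signature is injected as a Hanning-enveloped 4-12 Hz burst
  at F8 during the 1 s analysis window of each *medium*-SSD stop trial only,
  scaled per block, per drug group and by a simulated neuroticism coupling.

The injection is a phenomenological carrier of the biomarker's defining
contrast (conflict-specific excess rhythmicity), not a neural model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_design import (
    GO_RT_LOOKBACK,
    SessionSchedule,
    StaircaseState,
    build_session_schedule,
    medium_staircase_init,
    short_long_ssd,
    update_medium_staircase,
)

__all__ = [
    "ResponderModel",
    "EEGParams",
    "ConflictInjection",
    "BehavioralRecord",
    "ContinuousEEG",
    "ParticipantRecord",
    "CohortConfig",
    "sample_go_rt",
    "sample_ssrt",
    "race_outcome",
    "simulate_pretest",
    "simulate_behavior",
    "synthesize_eeg",
    "generate_participant",
    "generate_cohort",
]

FS = 128.0  #: sampling rate, Hz
CHANNELS = ("Fp1", "F7", "F3", "Fz", "F4", "F8")
SAMPLE_MS = 1000.0 / FS

#: trial timeline (s from trial onset): fixation circle, then the arrow
ARROW_ONSET_S = 0.5
TRIAL_DURATION_S = 2.5

GO_RT_FLOOR_MS = 150.0
SSRT_FLOOR_MS = 50.0


@dataclass(frozen=True)
class ResponderModel:
    """Generative behavioural parameters for one simulated participant.

    Go RTs are ex-Gaussian (mu, sigma, tau in ms; mean = mu + tau) and the
    stop process is Gaussian; on a small fraction of stop trials the stop
    process fails to launch at all (a trigger failure) and the go response
    is emitted regardless of the delay.  Defaults are calibrated so that a
    simulated cohort reproduces the published behavioural table: Go RT
    ~425 ms, SSRT estimate ~240 ms, and inhibition rates of ~79%/~50%/~9%
    on the short/medium/long staircases.  Without trigger failures those
    three inhibition rates are mutually inconsistent under a pure race:
    79% at the short delay requires a race so noisy that the long delay
    would be stopped far more than 9% of the time.
    """

    go_rt_mu: float = 395.0
    go_rt_sigma: float = 92.0
    go_rt_tau: float = 30.0
    ssrt_mean: float = 227.0
    ssrt_sd: float = 45.0
    trigger_failure_rate: float = 0.08
    choice_error_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.go_rt_sigma, self.go_rt_tau, self.ssrt_sd) < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0.0 <= self.choice_error_rate <= 1.0:
            raise ValueError("choice_error_rate must be in [0, 1]")


@dataclass(frozen=True)
class EEGParams:
    """Signal-model parameters for the synthetic EEG record."""

    fs: float = FS
    channels: tuple[str, ...] = CHANNELS
    pink_noise_scale: float = 20.0  # uV RMS per channel
    mains_hz: float = 50.0
    mains_amp: float = 2.0  # uV
    blink_rate_per_min: float = 8.0
    blink_amp_fp1: float = 120.0  # uV peak at Fp1
    blink_propagation: dict[str, float] = field(
        default_factory=lambda: {
            "Fp1": 1.0,
            "F7": 0.30,
            "F3": 0.45,
            "Fz": 0.40,
            "F4": 0.45,
            "F8": 0.30,
        }
    )
    band_pass: tuple[float, float] = (1.0, 36.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.band_pass[0] < self.band_pass[1] < self.fs / 2):
            raise ValueError("band_pass must lie within (0, fs/2)")


@dataclass(frozen=True)
class ConflictInjection:
    """Goal-conflict rhythmicity injected on medium-SSD stop trials.

    ``amplitude`` is the RMS (uV) of the band-limited burst before the
    Hanning envelope; block_profile mirrors the published observation that
    the conflict signature appears in blocks 1 and 3 but not block 2.
    """

    amplitude: float = 8.0
    band: tuple[float, float] = (4.0, 12.0)
    target_channel: str = "F8"
    pre_stop_s: float = 0.25
    window_s: float = 1.0
    block_profile: tuple[float, ...] = (1.0, 0.0, 1.0)
    drug_multiplier: float = 1.0
    trait_coupling: float = 0.0
    trait_z: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def effective_amplitude(self) -> float:
        """Amplitude after drug and trait scaling (block factor applied later)."""
        return max(
            0.0,
            self.amplitude * self.drug_multiplier * (1.0 + self.trait_coupling * self.trait_z),
        )


@dataclass
class BehavioralRecord:
    """Per-trial outcomes plus session-level summaries for one participant."""

    trials: pd.DataFrame  # index, block, kind, arrow, staircase, ssd_ms, onset_s, ...
    pretest_go_rt_ms: float
    median_go_rt_ms: float
    mean_medium_ssd_ms: float
    ssrt_ms: float
    p_inhibit: dict[str, float]


@dataclass
class ContinuousEEG:
    """Multichannel continuous signal (uV) with a sample-aligned event table."""

    data: np.ndarray  # channels x samples
    channels: tuple[str, ...]
    fs: float
    events: pd.DataFrame  # onset_s, duration_s, trial_type, trial_index, ...

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ParticipantRecord:
    id: str
    group: str | None
    traits: dict[str, float]
    schedule: SessionSchedule
    behavior: BehavioralRecord
    eeg: ContinuousEEG | None


def sample_go_rt(model: ResponderModel, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Ex-Gaussian Go RT draws, truncated at 150 ms."""
    rt = rng.normal(model.go_rt_mu, model.go_rt_sigma, size)
    if model.go_rt_tau > 0:
        rt = rt + rng.exponential(model.go_rt_tau, size)
    return np.maximum(rt, GO_RT_FLOOR_MS)


def sample_ssrt(model: ResponderModel, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Gaussian stop-signal RT draws, truncated at 50 ms."""
    return np.maximum(rng.normal(model.ssrt_mean, model.ssrt_sd, size), SSRT_FLOOR_MS)


def race_outcome(ssd_ms: float, ssrt_ms: float, go_rt_ms: float) -> bool:
    """Independent horse race: the stop wins iff it finishes before the go."""
    if min(ssd_ms, ssrt_ms, go_rt_ms) < 0:
        raise ValueError("race inputs must be non-negative")
    return ssd_ms + ssrt_ms < go_rt_ms


def _round_to_sample(ms: float) -> float:
    """Snap a latency to the 128 Hz sample grid (event times must align)."""
    return round(ms / SAMPLE_MS) * SAMPLE_MS


def simulate_pretest(model: ResponderModel, rng: np.random.Generator, n_trials: int = 32) -> float:
    """Pure-Go pretest establishing the participant's baseline Go RT (mean)."""
    return float(np.mean(sample_go_rt(model, rng, n_trials)))


def simulate_behavior(
    schedule: SessionSchedule,
    model: ResponderModel,
    seed: int | np.random.Generator = 0,
) -> BehavioralRecord:
    """Run the responder through the schedule, updating staircases online.

    Returns per-trial outcomes (onset times on the 128 Hz sample grid,
    realized SSDs, Go RTs, stop success) and the behavioural summaries the
    published tables report: median Go RT, mean medium SSD, SSRT (median Go
    RT minus mean medium SSD) and per-staircase inhibition rates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pretest = schedule.pretest_go_rt_ms
    medium = StaircaseState(name="medium", current_ssd_ms=medium_staircase_init(pretest))

    rows = []
    go_rt_history: list[float] = []
    t = 0.0
    for trial in schedule.trials:
        go_rt = float(sample_go_rt(model, rng, 1)[0])
        onset_s = t
        arrow_s = t + ARROW_ONSET_S
        short_ms, long_ms = short_long_ssd(go_rt_history, pretest)
        row = {
            "index": trial.index,
            "block": trial.block,
            "kind": trial.kind,
            "arrow": trial.arrow,
            "staircase": trial.staircase or "",
            "onset_s": onset_s,
            "arrow_onset_s": arrow_s,
            "ssd_ms": np.nan,
            "stop_onset_s": np.nan,
            "go_rt_ms": np.nan,
            "responded": False,
            "stop_success": np.nan,
        }
        if trial.kind == "go":
            correct = rng.random() >= model.choice_error_rate
            row.update(go_rt_ms=go_rt, responded=True, correct=correct)
            go_rt_history.append(go_rt)
        else:
            if trial.staircase == "short":
                ssd = short_ms
            elif trial.staircase == "long":
                ssd = long_ms
            else:
                ssd = medium.current_ssd_ms
            ssd = _round_to_sample(ssd)
            ssrt = float(sample_ssrt(model, rng, 1)[0])
            triggered = rng.random() >= model.trigger_failure_rate
            success = triggered and race_outcome(ssd, ssrt, go_rt)
            row.update(
                ssd_ms=ssd,
                stop_onset_s=arrow_s + ssd / 1000.0,
                stop_success=success,
                responded=not success,
                go_rt_ms=np.nan if success else go_rt,
                correct=True,
            )
            if trial.staircase == "medium":
                medium = update_medium_staircase(
                    medium, success, short_ms, long_ms, trial_index=trial.index
                )
        rows.append(row)
        t += TRIAL_DURATION_S

    trials = pd.DataFrame(rows)
    stop = trials[trials["kind"] == "stop"]
    go_rts = trials.loc[trials["kind"] == "go", "go_rt_ms"]
    medium_stop = stop[stop["staircase"] == "medium"]
    median_go = float(go_rts.median())
    mean_medium_ssd = float(medium_stop["ssd_ms"].mean())
    p_inhibit = {
        name: float(stop.loc[stop["staircase"] == name, "stop_success"].mean())
        for name in ("short", "medium", "long")
    }
    return BehavioralRecord(
        trials=trials,
        pretest_go_rt_ms=pretest,
        median_go_rt_ms=median_go,
        mean_medium_ssd_ms=mean_medium_ssd,
        ssrt_ms=median_go - mean_medium_ssd,
        p_inhibit=p_inhibit,
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / FS)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


_BLINK_DURATION_S = 0.3


def blink_waveform(fs: float = FS) -> np.ndarray:
    """Stereotyped biphasic blink shape, 300 ms, unit positive peak.

    A dominant positive lobe (lid closure potential) followed by a smaller
    negative rebound; fixed shape so template-recovery tests have ground
    truth.
    """
    n = int(round(_BLINK_DURATION_S * fs))
    t = np.arange(n) / fs
    lobe1 = np.exp(-0.5 * ((t - 0.10) / 0.035) ** 2)
    lobe2 = -0.35 * np.exp(-0.5 * ((t - 0.20) / 0.05) ** 2)
    w = lobe1 + lobe2
    return w / np.max(w)


def _band_burst(
    n: int, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise burst (or a pure tone if the band is a point).

    Within the band the amplitude spectrum is shaped by a Hann profile, so
    injected rhythmicity is strongest mid-band and tapers to zero at the band
    edges — an inverted-U spectral signature rather than a flat plateau.
    """
    lo, hi = band
    if lo == hi:
        t = np.arange(n) / FS
        x = np.cos(2 * np.pi * lo * t + rng.uniform(0, 2 * np.pi))
    else:
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, d=1.0 / FS)
        shape = np.zeros_like(f)
        inside = (f >= lo) & (f <= hi)
        shape[inside] = np.sin(np.pi * (f[inside] - lo) / (hi - lo)) ** 2
        x = np.fft.irfft(spec * shape, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_pass(data: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def synthesize_eeg(
    behavior: BehavioralRecord,
    eeg: EEGParams | None = None,
    inj: ConflictInjection | None = None,
    seed: int | np.random.Generator = 0,
    band_pass: bool = True,
) -> ContinuousEEG:
    """Continuous multichannel EEG for one simulated session.

    signal = pink noise + mains sinusoid + blink transients + conflict burst,
    optionally band-passed 1-36 Hz (zero-phase), with a sample-aligned event
    table (trial onsets, go stimuli, stop signals, responses).
    """
    eeg = eeg or EEGParams()
    inj = inj or ConflictInjection()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = behavior.trials
    fs = eeg.fs
    n_samples = int(round((trials["onset_s"].iloc[-1] + TRIAL_DURATION_S + 1.0) * fs))
    n_ch = len(eeg.channels)
    data = np.zeros((n_ch, n_samples))

    if eeg.pink_noise_scale > 0:
        for c in range(n_ch):
            data[c] += eeg.pink_noise_scale * _pink_noise(n_samples, rng)

    if eeg.mains_amp > 0:
        t = np.arange(n_samples) / fs
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        for c in range(n_ch):
            data[c] += eeg.mains_amp * np.sin(2 * np.pi * eeg.mains_hz * t + phases[c])

    blink_onsets_s: list[float] = []
    if eeg.blink_rate_per_min > 0 and eeg.blink_amp_fp1 > 0:
        wave = blink_waveform(fs)
        duration_s = n_samples / fs
        n_blinks = rng.poisson(eeg.blink_rate_per_min * duration_s / 60.0)
        onsets = np.sort(rng.uniform(0, duration_s - _BLINK_DURATION_S, n_blinks))
        for onset in onsets:
            i0 = int(round(onset * fs))
            seg = slice(i0, i0 + wave.size)
            amp = eeg.blink_amp_fp1 * rng.uniform(0.8, 1.2)
            for c, ch in enumerate(eeg.channels):
                data[c, seg] += amp * eeg.blink_propagation.get(ch, 0.0) * wave
            blink_onsets_s.append(float(onset))

    # conflict burst on medium-SSD stop trials at the target channel
    target_idx = eeg.channels.index(inj.target_channel)
    n_win = int(round(inj.window_s * fs))
    envelope = np.hanning(n_win)
    base_amp = inj.effective_amplitude
    medium_stops = trials[(trials["kind"] == "stop") & (trials["staircase"] == "medium")]
    for _, row in medium_stops.iterrows():
        b = int(row["block"])
        block_factor = inj.block_profile[b - 1] if b - 1 < len(inj.block_profile) else 1.0
        amp = base_amp * block_factor
        if amp <= 0:
            continue
        start = row["stop_onset_s"] - inj.pre_stop_s
        i0 = int(round(start * fs))
        if i0 < 0 or i0 + n_win > n_samples:
            continue
        burst = amp * _band_burst(n_win, inj.band, rng) * envelope
        data[target_idx, i0 : i0 + n_win] += burst

    if band_pass:
        data = _band_pass(data, eeg.band_pass, fs)

    events = _event_table(trials, blink_onsets_s)
    return ContinuousEEG(data=data, channels=tuple(eeg.channels), fs=fs, events=events)


def _event_table(trials: pd.DataFrame, blink_onsets_s: list[float]) -> pd.DataFrame:
    """BIDS-style long event table: one row per marker."""
    rows = []
    for _, r in trials.iterrows():
        rows.append(
            dict(
                onset=r["arrow_onset_s"],
                duration=0.0,
                trial_type=f"{r['kind']}_arrow",
                trial_index=int(r["index"]),
                block=int(r["block"]),
                staircase=r["staircase"],
                ssd=r["ssd_ms"] / 1000.0 if np.isfinite(r["ssd_ms"]) else np.nan,
                outcome=(
                    ("success" if r["stop_success"] else "fail")
                    if r["kind"] == "stop"
                    else ("response" if r["responded"] else "omission")
                ),
            )
        )
        if r["kind"] == "stop":
            rows.append(
                dict(
                    onset=r["stop_onset_s"],
                    duration=0.0,
                    trial_type="stop_signal",
                    trial_index=int(r["index"]),
                    block=int(r["block"]),
                    staircase=r["staircase"],
                    ssd=r["ssd_ms"] / 1000.0,
                    outcome="success" if r["stop_success"] else "fail",
                )
            )
    for onset in blink_onsets_s:
        rows.append(
            dict(
                onset=onset,
                duration=_BLINK_DURATION_S,
                trial_type="blink",
                trial_index=-1,
                block=-1,
                staircase="",
                ssd=np.nan,
                outcome="",
            )
        )
    return pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)


# -- cohort generation -------------------------------------------------------

#: trait distributions (mean, sd, low, high) matched to the published cohort
TRAIT_DISTRIBUTIONS = {
    "neuroticism": (9.0, 6.0, 0.0, 24.0),  # EPQ-R N
    "trait_anxiety": (38.0, 8.0, 20.0, 80.0),  # STAI-T
    "bis": (21.0, 8.0, 0.0, 28.0),  # BIS scale
}

DEFAULT_GROUPS = {"placebo": 8, "buspirone": 9, "triazolam": 9, "pregabalin": 8}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout plus the generative parameters shared by participants."""

    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    drug_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "placebo": 1.0,
            "buspirone": 0.3,
            "triazolam": 0.3,
            "pregabalin": 0.3,
        }
    )
    trait_coupling: float = 0.0
    responder: ResponderModel = field(default_factory=ResponderModel)
    eeg: EEGParams = field(default_factory=EEGParams)
    injection: ConflictInjection = field(default_factory=ConflictInjection)
    n_blocks: int = 3
    trials_per_block: int = 128
    seed: int = 0
    with_eeg: bool = True


def _draw_traits(rng: np.random.Generator) -> dict[str, float]:
    traits = {}
    for name, (mean, sd, lo, hi) in TRAIT_DISTRIBUTIONS.items():
        traits[name] = float(np.clip(round(rng.normal(mean, sd)), lo, hi))
    return traits


def generate_participant(
    pid: str,
    group: str | None,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ParticipantRecord:
    """One simulated participant: pretest, schedule, behaviour and EEG."""
    traits = _draw_traits(rng)
    pretest = simulate_pretest(config.responder, rng)
    schedule = build_session_schedule(
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        seed=int(rng.integers(2**31)),
        pretest_go_rt_ms=pretest,
    )
    behavior = simulate_behavior(schedule, config.responder, rng)
    eeg = None
    if config.with_eeg:
        neu_mean, neu_sd, _, _ = TRAIT_DISTRIBUTIONS["neuroticism"]
        inj = dataclasses.replace(
            config.injection,
            drug_multiplier=config.drug_multipliers.get(group, 1.0) if group else 1.0,
            trait_coupling=config.trait_coupling,
            trait_z=(traits["neuroticism"] - neu_mean) / neu_sd,
        )
        eeg = synthesize_eeg(behavior, config.eeg, inj, rng)
    return ParticipantRecord(
        id=pid, group=group, traits=traits, schedule=schedule, behavior=behavior, eeg=eeg
    )


def generate_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Simulate a full cohort with balanced drug groups.

    All randomness flows from ``config.seed`` through per-participant
    substreams (numpy SeedSequence spawning), so any participant can be
    regenerated independently and identical configs give identical cohorts.
    """
    config = config or CohortConfig()
    n_total = sum(config.groups.values())
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    records = []
    i = 0
    for group, n in config.groups.items():
        for k in range(n):
            rng = np.random.default_rng(streams[i])
            records.append(generate_participant(f"{group}_{k:02d}", group, config, rng))
            i += 1
    return records
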