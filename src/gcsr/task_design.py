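"""Three-staircase stop-signal task (SST) schedule engine.

The task is a choice reaction-time task (left/right arrow, button press) in
which one trial in every four carries an auditory stop signal at a variable
stop-signal delay (SSD).  Three nominal "staircases" deliver short, medium
and long SSDs:

* short and long SSDs are yoked to recent behaviour — 20% and 80% of the
  mean Go reaction time over the previous 16 Go trials;
* the medium SSD starts at 45% of the pretest Go RT and tracks stopping
  performance in 30 ms steps (up after a successful stop, down after a
  failure), so it converges on the ~50% inhibition point where the conflict
  between stopping and going is maximal;
* the medium SSD may never come within 50 ms of either of the other two.

This module is a pure schedule/state engine: it builds trial sequences,
updates staircase state and computes trial feedback.  It presents nothing
and times nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialSpec",
    "StaircaseState",
    "SessionSchedule",
    "Feedback",
    "build_session_schedule",
    "short_long_ssd",
    "medium_staircase_init",
    "update_medium_staircase",
    "feedback",
    "schedule_to_frame",
    "schedule_from_frame",
]

STAIRCASES = ("short", "medium", "long")

#: minimum separation (ms) between the medium SSD and either fixed staircase
MIN_SEPARATION_MS = 50.0
#: medium staircase step size (ms)
MEDIUM_STEP_MS = 30.0
#: short/long SSD fractions of the recent mean Go RT
SHORT_FRACTION = 0.20
LONG_FRACTION = 0.80
#: medium staircase starting point as a fraction of the pretest Go RT
MEDIUM_START_FRACTION = 0.45
#: number of Go RTs the short/long staircases look back over
GO_RT_LOOKBACK = 16
#: "slow" feedback threshold as a multiple of the pretest Go RT
SLOW_MULTIPLE = 1.5


class ConfigurationError(ValueError):
    """Raised when task parameters are mutually inconsistent."""


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial.

    ``ssd_ms`` and ``staircase`` are set only on stop trials; the SSD itself
    is realized at run time from the staircase state, so the scheduled value
    here is ``None`` until the session is simulated or run.
    """

    index: int
    block: int
    kind: Literal["go", "stop"]
    arrow: Literal["left", "right"]
    staircase: str | None = None
    ssd_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "stop" and self.staircase not in STAIRCASES:
            raise ValueError(f"stop trial requires a staircase, got {self.staircase!r}")
        if self.kind == "go" and (self.staircase is not None or self.ssd_ms is not None):
            raise ValueError("go trials carry no staircase or SSD")
        if self.ssd_ms is not None and self.ssd_ms < 0:
            raise ValueError("ssd_ms must be non-negative")


@dataclass(frozen=True)
class StaircaseState:
    """State of one SSD staircase; only the medium one steps."""

    name: str
    current_ssd_ms: float
    step_ms: float = MEDIUM_STEP_MS
    history: tuple = field(default_factory=tuple)

    def record(self, trial_index: int, ssd_ms: float, outcome: str) -> "StaircaseState":
        return replace(self, history=self.history + ((trial_index, ssd_ms, outcome),))


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered trial list for a full session plus its generation parameters."""

    trials: tuple[TrialSpec, ...]
    pretest_go_rt_ms: float
    seed: int
    n_blocks: int
    trials_per_block: int
    stop_every: int

    def block(self, b: int) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.block == b)

    @property
    def stop_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.kind == "stop")


def build_session_schedule(
    n_blocks: int = 3,
    trials_per_block: int = 128,
    stop_every: int = 4,
    seed: int = 0,
    pretest_go_rt_ms: float = 425.0,
) -> SessionSchedule:
    """Build a session schedule with one stop trial per window of ``stop_every``.

    Within each consecutive non-overlapping window of ``stop_every`` trials
    the stop trial occupies a uniformly random position, so the stop rate is
    exactly 1-in-``stop_every`` without the schedule being periodic and
    predictable.  Arrow directions are balanced left/right within each block.
    Staircase labels are assigned by cycling a per-block permutation of
    (short, medium, long); the permutation rotates across blocks so that over
    a 3-block session of 128 trials each staircase receives exactly 32 stop
    trials, and within any block the per-staircase counts differ by at most 1.
    """
    if n_blocks < 1:
        raise ConfigurationError("n_blocks must be >= 1")
    if trials_per_block % stop_every != 0:
        raise ConfigurationError(
            f"trials_per_block={trials_per_block} not divisible by stop_every={stop_every}"
        )
    rng = np.random.default_rng(seed)
    n_windows = trials_per_block // stop_every

    base_perm = list(rng.permutation(STAIRCASES))
    trials: list[TrialSpec] = []
    index = 0
    for b in range(1, n_blocks + 1):
        stop_positions = set(
            w * stop_every + int(rng.integers(stop_every)) for w in range(n_windows)
        )
        arrows = ["left"] * (trials_per_block // 2) + ["right"] * (
            trials_per_block - trials_per_block // 2
        )
        rng.shuffle(arrows)
        # rotate the staircase permutation each block: with 32 stop trials a
        # cycle of 3 leaves the *last* label of the permutation one short, and
        # rotating makes each staircase last exactly once per 3 blocks.
        perm = base_perm[(b - 1) % 3 :] + base_perm[: (b - 1) % 3]
        n_stop = 0
        for i in range(trials_per_block):
            if i in stop_positions:
                trials.append(
                    TrialSpec(
                        index=index,
                        block=b,
                        kind="stop",
                        arrow=arrows[i],
                        staircase=perm[n_stop % 3],
                    )
                )
                n_stop += 1
            else:
                trials.append(TrialSpec(index=index, block=b, kind="go", arrow=arrows[i]))
            index += 1
    return SessionSchedule(
        trials=tuple(trials),
        pretest_go_rt_ms=float(pretest_go_rt_ms),
        seed=int(seed),
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        stop_every=stop_every,
    )


def short_long_ssd(
    recent_go_rts_ms: Sequence[float],
    pretest_go_rt_ms: float | None = None,
) -> tuple[float, float]:
    """Short/long SSDs: 20% and 80% of the mean of the last 16 Go RTs.

    Before 16 Go RTs have accrued the mean of all available RTs is used; with
    none at all the pretest Go RT stands in.  Values are returned in
    continuous milliseconds (rounding to the EEG sample grid happens where
    events are realized).
    """
    rts = np.asarray(list(recent_go_rts_ms), dtype=float)
    if rts.size == 0:
        if pretest_go_rt_ms is None:
            raise ValueError("no Go RTs available and no pretest Go RT supplied")
        mean_rt = float(pretest_go_rt_ms)
    else:
        if np.any(rts < 0):
            raise ValueError("negative Go RT")
        mean_rt = float(np.mean(rts[-GO_RT_LOOKBACK:]))
    return SHORT_FRACTION * mean_rt, LONG_FRACTION * mean_rt


def medium_staircase_init(pretest_go_rt_ms: float) -> float:
    """Starting medium SSD: 45% of the pretest (pure-Go) reaction time."""
    if pretest_go_rt_ms <= 0:
        raise ValueError("pretest Go RT must be positive")
    return MEDIUM_START_FRACTION * float(pretest_go_rt_ms)


_EPS = 1e-9  # tolerance so boundary candidates (exactly 50 ms away) pass


def _admissible(x: float, short_ms: float, long_ms: float) -> bool:
    return (
        x >= -_EPS
        and abs(x - short_ms) >= MIN_SEPARATION_MS - _EPS
        and abs(x - long_ms) >= MIN_SEPARATION_MS - _EPS
    )


def update_medium_staircase(
    state: StaircaseState,
    stop_success: bool,
    short_ms: float,
    long_ms: float,
    trial_index: int = -1,
) -> StaircaseState:
    """Step the medium staircase and enforce the 50 ms separation rule.

    The proposed SSD is current + 30 ms after a successful stop and
    current - 30 ms after a failure.  If the proposal comes within 50 ms of
    the short or long SSD it is clamped to the nearest value exactly 50 ms
    from the conflicting staircase on the side the proposal lies; the result
    is floored at 0 ms.
    """
    if state.name != "medium":
        raise ValueError("only the medium staircase tracks responding")
    if short_ms > long_ms:
        raise ValueError(f"inconsistent schedule: short={short_ms} > long={long_ms}")
    proposed = state.current_ssd_ms + (state.step_ms if stop_success else -state.step_ms)
    proposed = max(proposed, 0.0)
    new = proposed
    if not _admissible(new, short_ms, long_ms):
        candidates = [
            c
            for c in (
                short_ms - MIN_SEPARATION_MS,
                short_ms + MIN_SEPARATION_MS,
                long_ms - MIN_SEPARATION_MS,
                long_ms + MIN_SEPARATION_MS,
            )
            if _admissible(c, short_ms, long_ms)
        ]
        if candidates:
            # prefer the candidate on the same side of its conflicting
            # staircase as the proposal; break remaining ties by distance
            conflict = short_ms if abs(proposed - short_ms) < MIN_SEPARATION_MS else long_ms
            side = 1.0 if proposed >= conflict else -1.0

            def rank(c: float) -> tuple[int, float]:
                same_side = 0 if (c - conflict) * side >= 0 else 1
                return (same_side, abs(c - proposed))

            new = min(candidates, key=rank)
        else:
            new = state.current_ssd_ms  # no admissible value; hold position
    outcome = "success" if stop_success else "fail"
    return replace(
        state.record(trial_index, new, outcome),
        current_ssd_ms=new,
    )


@dataclass(frozen=True)
class Feedback:
    smiley: bool
    slow_flag: bool


def feedback(
    trial: TrialSpec,
    responded: bool,
    correct_button: bool,
    go_rt_ms: float | None,
    pretest_go_rt_ms: float,
) -> Feedback:
    """Smiley/frowney plus 'slow' feedback for one completed trial.

    Stop trials earn a smiley for withholding the response.  Go trials earn a
    smiley for responding on the correct side, with an additional 'slow' flag
    when the Go RT strictly exceeds 1.5x the pretest Go RT (a deterrent
    against strategic slowing).
    """
    if responded and go_rt_ms is None:
        raise ValueError("responded trials need a go_rt_ms")
    if trial.kind == "stop":
        return Feedback(smiley=not responded, slow_flag=False)
    smiley = responded and correct_button
    slow = bool(
        responded and go_rt_ms is not None and go_rt_ms > SLOW_MULTIPLE * pretest_go_rt_ms
    )
    return Feedback(smiley=smiley, slow_flag=slow)


# -- tabular export ----------------------------------------------------------

_SCHEDULE_COLUMNS = ["index", "block", "kind", "arrow", "staircase", "ssd_ms"]


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """Schedule as a tidy trial table (one row per trial)."""
    rows = [
        {
            "index": t.index,
            "block": t.block,
            "kind": t.kind,
            "arrow": t.arrow,
            "staircase": t.staircase if t.staircase is not None else "",
            "ssd_ms": t.ssd_ms if t.ssd_ms is not None else np.nan,
        }
        for t in schedule.trials
    ]
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def schedule_from_frame(
    frame: pd.DataFrame,
    pretest_go_rt_ms: float,
    seed: int = 0,
    stop_every: int = 4,
) -> SessionSchedule:
    """Rebuild a SessionSchedule from a trial table written by schedule_to_frame."""
    trials = []
    for _, row in frame.iterrows():
        staircase = row["staircase"] if isinstance(row["staircase"], str) and row["staircase"] else None
        ssd = None if pd.isna(row["ssd_ms"]) else float(row["ssd_ms"])
        trials.append(
            TrialSpec(
                index=int(row["index"]),
                block=int(row["block"]),
                kind=row["kind"],
                arrow=row["arrow"],
                staircase=staircase,
                ssd_ms=ssd,
            )
        )
    blocks = sorted({t.block for t in trials})
    per_block = sum(1 for t in trials if t.block == blocks[0])
    return SessionSchedule(
        trials=tuple(trials),
        pretest_go_rt_ms=pretest_go_rt_ms,
        seed=seed,
        n_blocks=len(blocks),
        trials_per_block=per_block,
        stop_every=stop_every,
    )
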