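"""Two-down/one-up adaptive tracking for 3AFC modulation detection.

The engine implements the transformed up-down rule: the track steps toward
harder (shallower modulation) after two consecutive correct responses and
toward easier after any error, which converges on the 70.71%-correct point
of the listener's psychometric function.  Step size is 4 dB for the first
two reversals and a task-specific small step (1 dB temporal, 2 dB spectral)
for the remaining eight; the threshold is the mean of the last eight
reversal depths.

Around the adaptive core sit the attention controls used with child
listeners: a practice gate (9 of 10 consecutive correct at maximum depth,
within 30 trials; failure substitutes the maximum depth as the run's
threshold), interleaved easy trials at maximum depth every 4–6 adaptive
trials (more than two easy-trial errors invalidates the run), and two
track-stability statistics over the last eight reversals — their SD and the
mean length of excursion (MLE), the mean absolute difference between
consecutive reversals.

Depth bookkeeping uses a single convention for both tasks: depth in dB with
*larger = deeper modulation = easier*.  Temporal depths are ≤ 0
(20·log10(m)); spectral ripple depths are ≥ 0 (peak-to-trough dB, clamped
below at 0 since a ripple cannot have negative depth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .observers import ObserverParams, observer_response

__all__ = [
    "TrackConfig",
    "TrialRecord",
    "StaircaseState",
    "TrackResult",
    "SubjectThresholds",
    "run_practice",
    "update_depth",
    "run_track",
    "track_qc",
    "threshold_from_runs",
    "measure_task",
]

Task = Literal["temporal8", "temporal64", "spectral"]


@dataclass(frozen=True)
class TrackConfig:
    """Parameters of one adaptive track."""

    task: Task
    initial_depth_dB: float
    max_depth_dB: float  # deepest modulation allowed (easy end)
    step_large_dB: float = 4.0
    step_small_dB: float = 1.0
    n_reversals_large: int = 2
    n_reversals_total: int = 10
    n_alternatives: int = 3
    easy_gap_min: int = 4
    easy_gap_max: int = 6
    practice_criterion: int = 9
    practice_window: int = 10
    practice_max_trials: int = 30
    max_adaptive_trials: int = 150
    min_depth_dB: float = -np.inf  # hard floor (spectral: 0, a ripple depth cannot be negative)
    n_threshold_reversals: int = 8  # averaged for the threshold

    def __post_init__(self) -> None:
        if self.n_reversals_total <= self.n_reversals_large:
            raise ValueError("n_reversals_total must exceed n_reversals_large")
        if self.step_large_dB <= 0 or self.step_small_dB <= 0:
            raise ValueError("step sizes must be positive")
        if self.easy_gap_min < 1 or self.easy_gap_max < self.easy_gap_min:
            raise ValueError("easy-trial gap range invalid")

    @classmethod
    def preset(cls, task: Task) -> "TrackConfig":
        """Standard configuration for each of the three measured tasks."""
        if task == "temporal8" or task == "temporal64":
            return cls(task=task, initial_depth_dB=0.0, max_depth_dB=0.0, step_small_dB=1.0)
        if task == "spectral":
            return cls(
                task="spectral",
                initial_depth_dB=30.0,
                max_depth_dB=30.0,
                step_small_dB=2.0,
                min_depth_dB=0.0,
            )
        raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    depth_dB: float
    is_easy: bool
    target_position: int  # 1..3
    response_position: int  # 1..3
    correct: bool


@dataclass(frozen=True)
class StaircaseState:
    """Internal adaptive state threaded through :func:`update_depth`."""

    correct_streak: int = 0
    reversal_count: int = 0
    last_direction: int = 0  # sign of the last realized step; 0 = none yet
    reversal_at: float | None = None  # depth of a reversal logged this update, if any


@dataclass
class TrackResult:
    """One adaptive run: trial log, reversals, threshold, and QC."""

    config: TrackConfig
    trials: list[TrialRecord]
    reversal_depths_dB: list[float]
    threshold_dB: float | None
    sd_last8_dB: float | None
    mle_last8_dB: float | None
    easy_errors: int
    passed_practice: bool
    complete: bool

    @property
    def valid(self) -> bool:
        """Attention criterion: no more than two easy-trial errors."""
        return self.easy_errors <= 2

    def to_json(self) -> str:
        d = asdict(self)
        d["valid"] = self.valid
        return json.dumps(d, default=lambda o: None if o is None else str(o), indent=2)

    def write_log(self, path: str | Path) -> None:
        """JSON-lines trial log, one TrialRecord per line."""
        with open(path, "w") as fh:
            for tr in self.trials:
                fh.write(json.dumps(asdict(tr)) + "\n")


@dataclass(frozen=True)
class SubjectThresholds:
    run1_dB: float
    run2_dB: float

    @property
    def mean_dB(self) -> float:
        return (self.run1_dB + self.run2_dB) / 2.0


def _do_trial(
    observer: ObserverParams, depth_dB: float, n_alternatives: int, rng: np.random.Generator
) -> tuple[int, int, bool]:
    """Simulate one 3AFC trial: returns (target_pos, response_pos, correct)."""
    target = int(rng.integers(1, n_alternatives + 1))
    correct = observer_response(observer, depth_dB, rng)
    if correct:
        response = target
    else:
        others = [p for p in range(1, n_alternatives + 1) if p != target]
        response = int(others[rng.integers(0, len(others))])
    return target, response, correct


def run_practice(
    observer: ObserverParams, config: TrackConfig, rng: np.random.Generator
) -> tuple[bool, int, list[TrialRecord]]:
    """Practice gate at maximum depth.

    Passes as soon as some window of 10 consecutive trials contains at least
    9 correct responses; fails if no window qualifies within 30 trials.
    """
    log: list[TrialRecord] = []
    window: list[bool] = []
    for i in range(config.practice_max_trials):
        tgt, resp, correct = _do_trial(observer, config.max_depth_dB, config.n_alternatives, rng)
        log.append(TrialRecord(i, config.max_depth_dB, False, tgt, resp, correct))
        window.append(correct)
        if len(window) > config.practice_window:
            window.pop(0)
        if len(window) == config.practice_window and sum(window) >= config.practice_criterion:
            return True, i + 1, log
    return False, config.practice_max_trials, log


def update_depth(
    current_dB: float,
    state: StaircaseState,
    correct: bool,
    config: TrackConfig,
) -> tuple[float, StaircaseState]:
    """One two-down/one-up update.

    Two consecutive correct responses step toward harder (smaller dB) and
    reset the streak; any error steps toward easier (larger dB).  A reversal
    is logged at the current depth when the realized step direction changes;
    the step size drops from 4 dB to the small step on the first step after
    the second reversal.  Depth is clamped to [min_depth_dB, max_depth_dB];
    a step that cannot move (already at a clamp) changes neither the depth
    nor the direction bookkeeping.
    """
    if correct:
        streak = state.correct_streak + 1
        if streak < 2:
            return current_dB, replace(state, correct_streak=streak, reversal_at=None)
        direction = -1  # harder
        streak = 0
    else:
        direction = +1  # easier
        streak = 0

    # A clamped step realizes no movement: streak logic above still applied.
    at_clamp = (direction > 0 and current_dB >= config.max_depth_dB) or (
        direction < 0 and current_dB <= config.min_depth_dB
    )
    if at_clamp:
        return current_dB, replace(state, correct_streak=streak, reversal_at=None)

    reversal_at = None
    n_rev = state.reversal_count
    if state.last_direction != 0 and direction != state.last_direction:
        reversal_at = current_dB
        n_rev += 1

    step = config.step_large_dB if n_rev < config.n_reversals_large else config.step_small_dB
    next_dB = float(
        np.clip(current_dB + direction * step, config.min_depth_dB, config.max_depth_dB)
    )
    return next_dB, StaircaseState(
        correct_streak=streak,
        reversal_count=n_rev,
        last_direction=direction,
        reversal_at=reversal_at,
    )


def track_qc(reversal_depths: Sequence[float], n_last: int = 8) -> tuple[float, float]:
    """Track-stability statistics over the last ``n_last`` reversals.

    Returns ``(sd, mle)``: the sample SD (n−1 denominator) of the last eight
    reversal depths, and the mean length of excursion — the mean absolute
    difference between each consecutive pair among those eight.
    """
    if len(reversal_depths) < n_last:
        raise ValueError(f"need at least {n_last} reversals, got {len(reversal_depths)}")
    last = np.asarray(reversal_depths[-n_last:], dtype=float)
    sd = float(np.std(last, ddof=1))
    mle = float(np.mean(np.abs(np.diff(last))))
    return sd, mle


def run_track(
    observer: ObserverParams,
    config: TrackConfig,
    rng: np.random.Generator,
    run_practice_gate: bool = True,
) -> TrackResult:
    """One complete adaptive run.

    Easy trials at maximum depth are interleaved every 4–6 adaptive trials
    (uniform integer gap, redrawn after each easy trial); they probe
    attention only and never touch the staircase state.  The run ends when
    ``n_reversals_total`` reversals are logged (threshold = mean of the last
    eight) or at the safety cap (flagged incomplete).  A failed practice
    substitutes the maximum depth as the threshold for this run.
    """
    passed = True
    trials: list[TrialRecord] = []
    if run_practice_gate:
        passed, _, practice_log = run_practice(observer, config, rng)
        if not passed:
            return TrackResult(
                config=config,
                trials=practice_log,
                reversal_depths_dB=[],
                threshold_dB=config.max_depth_dB,
                sd_last8_dB=None,
                mle_last8_dB=None,
                easy_errors=0,
                passed_practice=False,
                complete=True,
            )

    depth = config.initial_depth_dB
    state = StaircaseState()
    reversals: list[float] = []
    easy_errors = 0
    adaptive_since_easy = 0
    next_easy_gap = int(rng.integers(config.easy_gap_min, config.easy_gap_max + 1))
    n_adaptive = 0
    idx = 0

    while n_adaptive < config.max_adaptive_trials and len(reversals) < config.n_reversals_total:
        if adaptive_since_easy == next_easy_gap:
            tgt, resp, correct = _do_trial(
                observer, config.max_depth_dB, config.n_alternatives, rng
            )
            trials.append(TrialRecord(idx, config.max_depth_dB, True, tgt, resp, correct))
            easy_errors += int(not correct)
            adaptive_since_easy = 0
            next_easy_gap = int(rng.integers(config.easy_gap_min, config.easy_gap_max + 1))
            idx += 1
            continue

        tgt, resp, correct = _do_trial(observer, depth, config.n_alternatives, rng)
        trials.append(TrialRecord(idx, depth, False, tgt, resp, correct))
        depth, state = update_depth(depth, state, correct, config)
        if state.reversal_at is not None:
            reversals.append(state.reversal_at)
        n_adaptive += 1
        adaptive_since_easy += 1
        idx += 1

    complete = len(reversals) >= config.n_reversals_total
    if complete:
        threshold = float(np.mean(reversals[-config.n_threshold_reversals :]))
        sd, mle = track_qc(reversals, config.n_threshold_reversals)
    else:
        threshold, sd, mle = None, None, None
    return TrackResult(
        config=config,
        trials=trials,
        reversal_depths_dB=reversals,
        threshold_dB=threshold,
        sd_last8_dB=sd,
        mle_last8_dB=mle,
        easy_errors=easy_errors,
        passed_practice=passed,
        complete=complete,
    )


def threshold_from_runs(run1: TrackResult, run2: TrackResult) -> float:
    """Mean threshold across the two runs of a task."""
    for r in (run1, run2):
        if r.threshold_dB is None:
            raise ValueError("cannot average an incomplete run without a threshold")
    return (run1.threshold_dB + run2.threshold_dB) / 2.0


def measure_task(
    observer: ObserverParams,
    config: TrackConfig,
    rng: np.random.Generator,
    n_runs: int = 2,
    run_practice_gate: bool = True,
) -> tuple[SubjectThresholds, list[TrackResult]]:
    """Run the standard two runs of one task and average the thresholds."""
    if n_runs != 2:
        raise ValueError("the measurement protocol averages exactly two runs")
    results = [run_track(observer, config, rng, run_practice_gate) for _ in range(n_runs)]
    threshold_from_runs(results[0], results[1])  # validates completeness
    st = SubjectThresholds(results[0].threshold_dB, results[1].threshold_dB)
    return st, results
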