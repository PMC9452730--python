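"""The simulated closed-loop neurofeedback session.

Every 2-second volume is preprocessed with the stored normalization
parameters, restricted to the classifier's informative voxels and classified
against the tutor model. During task blocks a correct classification adds
one bar to the on-screen thermometer and an incorrect one removes one
(clamped to the display range); at each rest block the thermometer resets to
the rounded mean of the previous task block's trajectory. Run accuracy is
100 x correct / 210 in the default mode (rest volumes count in the
denominator but can never be correct, ceiling 160/210 = 76.19%); an
alternative mode scores task volumes only (denominator 160). The monetary
reward is 1.5 USD up to 50% accuracy, then +2 USD per started 5% above 50.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .images import BoldRun
from .mvpa import EffectMapModel, OnlineDetrender
from .paradigm import Condition, Paradigm
from .preprocess import NormParams, online_preprocess_run

DEFAULT_MAX_BARS = 10


@dataclass
class VolumeOutcome:
    volume_index: int
    expected: Condition
    predicted: Condition | None    # None on rest volumes (no classification shown)
    correct: bool
    decision_value: float | None
    bar_count: int


@dataclass
class FeedbackState:
    """Thermometer display state and per-volume bookkeeping."""

    bar_count: int
    max_bars: int = DEFAULT_MAX_BARS
    current_block: int = -1
    log: list[VolumeOutcome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.bar_count <= self.max_bars:
            raise ValueError("bar_count outside [0, max_bars]")


@dataclass
class RunResult:
    outcomes: list[VolumeOutcome]
    accuracy_percent: float
    reward_usd: float
    bar_trajectory: list[int]
    events: list[str] = field(default_factory=list)
    per_volume_seconds: list[float] = field(default_factory=list)


def classify_volume(
    x_selected: np.ndarray, model: EffectMapModel, expected: Condition
) -> tuple[Condition, bool, float]:
    """Classify one volume's selected-voxel features against the tutor model.

    Returns (predicted, correct, decision value); the tie at decision value
    exactly 0 resolves to HAPPY.
    """
    d = model.decision_value(np.asarray(x_selected, float))
    predicted = Condition.HAPPY if d >= 0 else Condition.MOTOR
    return predicted, predicted == expected, d


def update_thermometer(state: FeedbackState, correct: bool,
                       expected: Condition) -> FeedbackState:
    """Add (correct) or subtract (incorrect) one bar, clamped to the range."""
    if expected == Condition.REST:
        raise ValueError("thermometer is not updated on REST volumes; see rest_reset")
    delta = 1 if correct else -1
    state.bar_count = min(state.max_bars, max(0, state.bar_count + delta))
    return state


def rest_reset(state: FeedbackState,
               previous_block_trajectory: list[int] | None) -> FeedbackState:
    """Reset the thermometer on entering a rest block.

    The new level is the mean of the previous task block's bar trajectory,
    rounded half to even; the very first rest block (no task block yet)
    resets to the midpoint of the display range.
    """
    if previous_block_trajectory:
        state.bar_count = int(round(float(np.mean(previous_block_trajectory))))
    else:
        state.bar_count = state.max_bars // 2
    return state


def run_accuracy(outcomes: list[VolumeOutcome], mode: str = "all_volumes",
                 expected_volumes: int = 210) -> float:
    """Percent accuracy of one run.

    mode="all_volumes" (default): 100 x correct / total volumes — the rest
    volumes stay in the denominator and are never correct, so the ceiling
    with the default paradigm is 160/210 = 76.19%.
    mode="task_only": 100 x correct / task volumes.
    """
    if len(outcomes) != expected_volumes:
        raise ValueError(
            f"expected {expected_volumes} outcomes, got {len(outcomes)}"
        )
    n_correct = sum(o.correct for o in outcomes)
    if mode == "all_volumes":
        denom = len(outcomes)
    elif mode == "task_only":
        denom = sum(o.expected != Condition.REST for o in outcomes)
    else:
        raise ValueError(f"unknown accuracy mode {mode!r}")
    return 100.0 * n_correct / denom


def reward(accuracy_percent: float) -> float:
    """Monetary reward in USD for one run.

    1.5 USD at or below 50% accuracy, then 2 USD more for every started 5%
    band above 50 (51-55% -> 3.5, 56-60% -> 5.5, 61-65% -> 7.5, ...).
    """
    if not 0.0 <= accuracy_percent <= 100.0:
        raise ValueError("accuracy_percent must be in [0, 100]")
    if accuracy_percent <= 50.0:
        return 1.5
    return 1.5 + 2.0 * math.ceil((accuracy_percent - 50.0) / 5.0)


def run_feedback(
    run: BoldRun,
    model: EffectMapModel,
    norm_params: NormParams,
    paradigm: Paradigm,
    max_bars: int = DEFAULT_MAX_BARS,
    accuracy_mode: str = "all_volumes",
    online_detrend: bool = True,
    label_shift: int = 0,
) -> RunResult:
    """Play one full run through the closed loop.

    The volume stream is preprocessed with the stored normalization
    parameters (never re-estimated), linearly detrended with a running fit
    (mirroring the offline detrend the classifier was trained on),
    classified per TR, and fed to the thermometer; the reward event is
    logged for the last 3 s of the run.
    """
    if run.n_volumes != paradigm.n_volumes:
        raise ValueError("run length does not match paradigm")
    # optional hemodynamic delay: expected labels (and block bookkeeping)
    # lag the stimulus schedule by `label_shift` TRs
    labels = paradigm.volume_labels()
    block_of = paradigm.volume_block_index()
    if label_shift:
        if label_shift < 0:
            raise ValueError("label_shift must be >= 0")
        labels = [Condition.REST] * label_shift + labels[:-label_shift]
        block_of = [block_of[0]] * label_shift + block_of[:-label_shift]

    pre = online_preprocess_run(run, norm_params)
    flat = pre.data.reshape(-1, pre.n_volumes)
    feats = flat[model.selected].T  # (t, n_selected)
    if online_detrend:
        det = OnlineDetrender(feats.shape[1])
        feats = np.stack([
            det.update(feats[t], is_rest=labels[t] == Condition.REST)
            for t in range(len(feats))
        ])
    state = FeedbackState(bar_count=max_bars // 2, max_bars=max_bars)
    block_traj: list[int] = []
    trajectory: list[int] = []
    times: list[float] = []
    events: list[str] = []
    seen_task_block = False

    for t in range(pre.n_volumes):
        tic = time.perf_counter()
        expected = labels[t]
        if block_of[t] != state.current_block:
            if labels[t] == Condition.REST:
                rest_reset(state, block_traj if seen_task_block else None)
            block_traj = []
            state.current_block = block_of[t]
        if expected == Condition.REST:
            # no classification is shown during rest; never scores as correct
            state.log.append(VolumeOutcome(t, expected, None, False, None,
                                           state.bar_count))
        else:
            seen_task_block = True
            predicted, correct, d = classify_volume(feats[t], model, expected)
            update_thermometer(state, correct, expected)
            block_traj.append(state.bar_count)
            state.log.append(VolumeOutcome(t, expected, predicted, correct, d,
                                           state.bar_count))
        trajectory.append(state.bar_count)
        times.append(time.perf_counter() - tic)

    acc = run_accuracy(state.log, mode=accuracy_mode,
                       expected_volumes=paradigm.n_volumes)
    usd = reward(acc)
    events.append(
        f"reward {usd:.2f} USD displayed during final 3 s "
        f"(volumes {pre.n_volumes - 2}-{pre.n_volumes - 1})"
    )
    return RunResult(state.log, acc, usd, trajectory, events, times)


def run_session(
    runs: list[BoldRun],
    model: EffectMapModel,
    norm_params: NormParams,
    paradigm: Paradigm,
    **kwargs,
) -> list[RunResult]:
    """One training day: the given runs (4 in the study protocol) in order."""
    if model is None or paradigm is None:
        raise ValueError("run_session requires a trained model and a paradigm")
    return [run_feedback(r, model, norm_params, paradigm, **kwargs) for r in runs]
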