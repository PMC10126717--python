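"""Physical-prosthesis control layer.

Two mechanisms sit between the streaming decoder and the prosthetic hand,
both designed to prevent the sudden movements a purely discrete
classifier would command:

* a **grip-selection filter** — a newly decoded grip must persist for
  250 ms (five consecutive 50 ms bins) before the hand actuates it;
* a **velocity ramp** — after a grip change the proportional speed
  command is attenuated linearly from 0 back to the raw input over
  500 ms.

The module also scores the segmented activity-of-daily-living task: each
segment of the task requires transitioning into a specified grip; a
repetition is correct iff the first actuated grip equals the required
one. With 5 segments × 5 repetitions × 5 trials the maximum number of
possible transition errors is 125.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .decoders import HmmNbModel, forward_filter
from .signal_processing import FeatureSequence


@dataclass(frozen=True)
class ControllerConfig:
    grip_threshold_ms: float = 250.0
    ramp_duration_ms: float = 500.0
    bin_width_ms: float = 50.0
    grips: tuple[str, ...] = ("rest", "fist", "pinch", "point", "open")

    def __post_init__(self) -> None:
        for v in (self.grip_threshold_ms, self.ramp_duration_ms):
            if abs(v / self.bin_width_ms - round(v / self.bin_width_ms)) > 1e-9:
                raise ValueError("thresholds must be multiples of bin_width")


@dataclass(frozen=True)
class ControllerState:
    active_grip: str = "rest"
    candidate_grip: str | None = None
    candidate_elapsed_ms: float = 0.0
    ramp_elapsed_ms: float = float("inf")  # fully ramped at start
    commanded_speed: float = 0.0
    just_actuated: bool = False


def step(
    state: ControllerState,
    config: ControllerConfig,
    decoded: str,
    proportional_input: float = 1.0,
) -> ControllerState:
    """Advance the controller by one decoder bin.

    A decoded class differing from the active grip accumulates candidate
    time (a single bin of any other class resets it — strict continuity);
    at ``grip_threshold`` the new grip actuates and the velocity ramp
    restarts from zero. ``commanded_speed`` is the proportional input
    attenuated by ``min(1, ramp_elapsed / ramp_duration)``, evaluated
    before the ramp clock advances, so it is exactly 0 on the actuation
    bin and reaches the raw input only after ``ramp_duration``.
    """
    if not 0.0 <= proportional_input <= 1.0:
        raise ValueError("proportional input must be in [0, 1]")
    dt = config.bin_width_ms
    active = state.active_grip
    candidate = state.candidate_grip
    elapsed = state.candidate_elapsed_ms
    ramp = state.ramp_elapsed_ms
    actuated = False

    if decoded == active:
        candidate, elapsed = None, 0.0
    elif decoded == candidate:
        elapsed += dt
    else:
        candidate, elapsed = decoded, dt
    if candidate is not None and elapsed >= config.grip_threshold_ms:
        active, candidate, elapsed = candidate, None, 0.0
        ramp = 0.0
        actuated = True

    speed = proportional_input * min(1.0, ramp / config.ramp_duration_ms)
    return ControllerState(
        active_grip=active,
        candidate_grip=candidate,
        candidate_elapsed_ms=elapsed,
        ramp_elapsed_ms=ramp + dt,
        commanded_speed=speed,
        just_actuated=actuated,
    )


def run_controller(
    config: ControllerConfig,
    decoded_sequence: Sequence[str],
    proportional: Sequence[float] | float = 1.0,
    initial: ControllerState | None = None,
) -> list[ControllerState]:
    """Apply the grip filter + ramp to a whole decoded sequence."""
    state = initial or ControllerState()
    if np.isscalar(proportional):
        proportional = [float(proportional)] * len(decoded_sequence)
    states = []
    for d, p in zip(decoded_sequence, proportional):
        state = step(state, config, str(d), p)
        states.append(state)
    return states


@dataclass(frozen=True)
class SegmentedTaskPlan:
    """Ordered task segments, each requiring a transition into a grip."""

    segments: tuple[tuple[str, str], ...]  # (required grip, description)
    repetitions: int = 5
    trials: int = 5

    @property
    def max_transition_errors(self) -> int:
        return len(self.segments) * self.repetitions * self.trials


def coffee_task_plan(repetitions: int = 5, trials: int = 5) -> SegmentedTaskPlan:
    """The five-segment coffee-making task: each segment transitions into
    one of the four functional grips or hand open."""
    return SegmentedTaskPlan(
        segments=(
            ("fist", "pick up the cup of water"),
            ("open", "release the cup into the brewer"),
            ("pinch", "pick up the coffee pod"),
            ("point", "press the brew button"),
            ("fist", "pick up the finished cup"),
        ),
        repetitions=repetitions,
        trials=trials,
    )


@dataclass
class SegmentedTaskResult:
    correct: int
    incorrect: int
    accuracy_percent: float  # unrounded
    accuracy_percent_rounded: int
    max_transition_errors: int
    attempts: list[tuple[str, str | None]]  # (required, first actuated)


def score_attempts(attempts: Sequence[tuple[str, str | None]]) -> SegmentedTaskResult:
    """Score segment attempts: correct iff the first actuated grip equals
    the required grip (no actuation counts as incorrect)."""
    correct = sum(1 for req, act in attempts if act == req)
    total = len(attempts)
    acc = 100.0 * correct / total if total else 0.0
    return SegmentedTaskResult(
        correct=correct,
        incorrect=total - correct,
        accuracy_percent=acc,
        accuracy_percent_rounded=int(round(acc)),
        max_transition_errors=total,
        attempts=list(attempts),
    )


def run_segmented_task(
    decoder: HmmNbModel,
    config: ControllerConfig,
    plan: SegmentedTaskPlan,
    stream_source: Callable[[str, int, float], FeatureSequence],
    seed: int = 0,
    attempt_duration_ms: float = 2000.0,
) -> SegmentedTaskResult:
    """Simulate the segmented task end to end.

    For every repetition of every segment in every trial, a feature
    stream for the required grip is decoded and fed through the grip
    filter; the first grip the controller actuates is compared with the
    requirement. Between repetitions the hand is opened (controller reset
    with hand open active), mirroring release-and-regrasp.
    """
    root = np.random.SeedSequence(seed)
    seeds = iter(root.spawn(plan.trials * len(plan.segments) * plan.repetitions))
    attempts: list[tuple[str, str | None]] = []
    for _trial in range(plan.trials):
        for required, _desc in plan.segments:
            for _rep in range(plan.repetitions):
                seed_k = int(next(seeds).generate_state(1)[0] % (2**31))
                feats = stream_source(required, seed_k, attempt_duration_ms)
                outputs = forward_filter(decoder, feats).labels
                state = ControllerState(active_grip="open")
                first: str | None = None
                for d in outputs:
                    state = step(state, config, str(d))
                    if state.just_actuated and state.active_grip != "rest":
                        first = state.active_grip
                        break
                attempts.append((required, first))
    return score_attempts(attempts)
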