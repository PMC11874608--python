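"""Adaptive 2AFC threshold measurement for relative-phase perception.

Two independent but interleaved transformed 1-up/2-down staircases control
how far the comparison display's relative phase sits from the 90° standard,
one for comparisons below 90° and one above.  Difficulty steps down 5.48°
(54.88 % of the 10° up-step, the standard ratio for this transformed rule)
after two consecutive correct responses and up 10° after any error; before
the first error the staircase is in an initial descent, stepping down on
every correct response.  Each staircase stops after 8 reversals, and the
threshold is the mean reversal difference excluding the first reversal,
averaged across the two staircases.  This rule converges on the 70.71 %
correct point of the observer's psychometric function.

The module also generates position-perturbed displays: the top dot's
amplitude is redrawn at random every half-cycle (the bottom dot's is yoked
at half of it), which destroys relative-position information while leaving
the mean relative phase intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, StaircaseError
from .synthetic import ObserverModel, OscillatorParams, TrialTimeSeries, observer_respond

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "SessionLog",
    "PerturbedDisplaySpec",
    "staircase_init",
    "staircase_update",
    "run_2afc_session",
    "estimate_threshold",
    "generate_perturbed_display",
]

#: Smallest allowed phase difference, degrees; at 0° the 2AFC is undefined.
DIFFERENCE_FLOOR = 1.0


@dataclass(frozen=True)
class StaircaseConfig:
    initial_difference: float = 30.0  # degrees
    step_up: float = 10.0  # degrees
    down_ratio: float = 0.5488  # step_down = down_ratio * step_up
    n_reversal_stop: int = 8
    side: str = "below_90"  # below_90 | above_90

    def __post_init__(self) -> None:
        if not 0.0 < self.down_ratio < 1.0:
            raise InvalidParameterError("down_ratio must be in (0, 1)")
        if self.step_up <= 0 or self.initial_difference <= 0:
            raise InvalidParameterError("steps and initial difference must be > 0")
        if self.n_reversal_stop < 2:
            raise InvalidParameterError("need at least 2 reversals to stop")
        if self.side not in ("below_90", "above_90"):
            raise InvalidParameterError(f"unknown side {self.side!r}")

    @property
    def step_down(self) -> float:
        return self.down_ratio * self.step_up


@dataclass(frozen=True)
class StaircaseState:
    """Full state of one transformed 1-up/2-down staircase."""

    current_difference: float
    mode: str = "initial_descent"  # initial_descent | updown
    consecutive_correct: int = 0
    reversals: tuple[float, ...] = ()
    last_direction: str = "none"  # none | down | up
    finished: bool = False


def staircase_init(config: StaircaseConfig) -> StaircaseState:
    """Fresh staircase at the configured initial difference (30° by default)."""
    return StaircaseState(current_difference=config.initial_difference)


def staircase_update(state: StaircaseState, correct: bool,
                     config: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one judged trial.

    During the initial descent every correct response steps down; the first
    error records the first reversal, steps up, and switches to the
    1-up/2-down rule proper.  Thereafter two consecutive correct responses
    step down and any error steps up, with a reversal recorded (at the
    difference just presented) whenever the step direction changes.  The
    difference is floored at 1° and the staircase finishes at the configured
    reversal count.
    """
    if state.finished:
        raise StaircaseError("staircase already finished")
    presented = state.current_difference
    reversals = state.reversals

    if state.mode == "initial_descent":
        if correct:
            return replace(
                state,
                current_difference=max(presented - config.step_down, DIFFERENCE_FLOOR),
                last_direction="down",
            )
        reversals = reversals + (presented,)
        return StaircaseState(
            current_difference=presented + config.step_up,
            mode="updown",
            consecutive_correct=0,
            reversals=reversals,
            last_direction="up",
            finished=len(reversals) >= config.n_reversal_stop,
        )

    if correct:
        cc = state.consecutive_correct + 1
        if cc < 2:
            return replace(state, consecutive_correct=cc)
        if state.last_direction == "up":
            reversals = reversals + (presented,)
        return StaircaseState(
            current_difference=max(presented - config.step_down, DIFFERENCE_FLOOR),
            mode="updown",
            consecutive_correct=0,
            reversals=reversals,
            last_direction="down",
            finished=len(reversals) >= config.n_reversal_stop,
        )
    if state.last_direction == "down":
        reversals = reversals + (presented,)
    return StaircaseState(
        current_difference=presented + config.step_up,
        mode="updown",
        consecutive_correct=0,
        reversals=reversals,
        last_direction="up",
        finished=len(reversals) >= config.n_reversal_stop,
    )


@dataclass
class SessionLog:
    """Every judged trial plus the final state of both staircases."""

    trials: list[dict]  # {"trial", "side", "difference_deg", "correct"}
    states: dict[str, StaircaseState]
    configs: dict[str, StaircaseConfig]


def run_2afc_session(observer: ObserverModel,
                     configs: tuple[StaircaseConfig, StaircaseConfig] | None = None,
                     seed: int | np.random.Generator = 0) -> SessionLog:
    """Run a full judgement session: two interleaved staircases (one per side
    of 90°) against a simulated observer, until both have finished.

    The next staircase is picked uniformly at random among the unfinished
    ones; the same seeded generator drives both the interleaving and the
    observer's responses, so a fixed seed reproduces the session exactly.
    """
    if configs is None:
        configs = (StaircaseConfig(side="below_90"), StaircaseConfig(side="above_90"))
    sides = tuple(c.side for c in configs)
    if set(sides) != {"below_90", "above_90"}:
        raise InvalidParameterError("need one staircase per side of 90°")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states = {c.side: staircase_init(c) for c in configs}
    config_by_side = {c.side: c for c in configs}
    trials: list[dict] = []
    trial_no = 0
    while not all(s.finished for s in states.values()):
        open_sides = [side for side, s in states.items() if not s.finished]
        side = open_sides[int(rng.integers(len(open_sides)))]
        state = states[side]
        delta = state.current_difference
        correct = observer_respond(observer, delta, rng)
        states[side] = staircase_update(state, correct, config_by_side[side])
        trial_no += 1
        trials.append({"trial": trial_no, "side": side,
                       "difference_deg": delta, "correct": correct})
    return SessionLog(trials=trials, states=states, configs=config_by_side)


def estimate_threshold(log: SessionLog) -> float:
    """Threshold from a finished session: per staircase, the mean reversal
    difference excluding the first reversal; then the mean of the two
    per-staircase values."""
    per_side = []
    for side, state in log.states.items():
        if not state.finished:
            raise StaircaseError(f"staircase {side} has not finished")
        if len(state.reversals) < 2:
            raise StaircaseError(f"staircase {side} has fewer than 2 reversals")
        per_side.append(float(np.mean(state.reversals[1:])))
    return float(np.mean(per_side))


@dataclass(frozen=True)
class PerturbedDisplaySpec:
    """Per-half-cycle amplitudes of a position-perturbed display."""

    half_cycle_amplitudes_top: tuple[float, ...]
    half_cycle_amplitudes_bottom: tuple[float, ...]
    relative_phase: float  # degrees
    frequency: float  # Hz
    duration: float  # s

    def __post_init__(self) -> None:
        top = self.half_cycle_amplitudes_top
        bottom = self.half_cycle_amplitudes_bottom
        if len(top) != len(bottom):
            raise InvalidParameterError("top/bottom amplitude lists differ in length")
        if any(not math.isclose(b, 0.5 * t) for t, b in zip(top, bottom)):
            raise InvalidParameterError("bottom amplitudes must be half the top's")
        if any(t <= 0 for t in top):
            raise InvalidParameterError("amplitudes must be positive")


def generate_perturbed_display(
    osc: OscillatorParams,
    relative_phase: float,
    max_amplitude: float | None = None,
    seed: int | np.random.Generator = 0,
    min_amplitude_fraction: float = 0.25,
) -> tuple[PerturbedDisplaySpec, TrialTimeSeries]:
    """Build a position-perturbed display pair at a fixed relative phase.

    The top dot's amplitude is redrawn uniformly on
    [``min_amplitude_fraction`` x nominal, ``max_amplitude``] at each of its
    own zero crossings (half-cycle boundaries), keeping its instantaneous
    phase ``omega t`` continuous; the bottom dot runs at the constant phase
    offset ``relative_phase`` with amplitude yoked to half the top's.  The
    lower bound keeps every half-cycle crossing the screen midline; the
    upper bound keeps the dot on screen.
    """
    if max_amplitude is None:
        max_amplitude = osc.amplitude
    if max_amplitude <= 0:
        raise InvalidParameterError("max_amplitude must be > 0")
    n_half_cycles = int(math.floor(2.0 * osc.frequency * osc.duration))
    if n_half_cycles < 2:
        raise InvalidParameterError("duration must cover at least 2 half-cycles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lo = min_amplitude_fraction * osc.amplitude
    if lo > max_amplitude:
        raise InvalidParameterError("amplitude floor exceeds max_amplitude")
    amps_top = rng.uniform(lo, max_amplitude, size=n_half_cycles)

    t = osc.time_grid()
    # index of the top dot's half-cycle at each sample
    half_idx = np.minimum((2.0 * osc.frequency * t).astype(int), n_half_cycles - 1)
    a_top = amps_top[half_idx]
    base = osc.omega * t
    phi = math.radians(relative_phase)
    top = a_top * np.sin(base)
    bottom = 0.5 * a_top * np.sin(base - phi)

    spec = PerturbedDisplaySpec(
        half_cycle_amplitudes_top=tuple(amps_top),
        half_cycle_amplitudes_bottom=tuple(0.5 * amps_top),
        relative_phase=float(relative_phase),
        frequency=osc.frequency,
        duration=osc.duration,
    )
    trial = TrialTimeSeries(time=t, left_position=top, right_position=bottom,
                            target_phase=float(relative_phase))
    return spec, trial
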