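"""Training-session logic: coordination feedback, knowledge of results,
bandwidth fading, and progression/stop rules.

A training session is 30 trials at the 90° target.  Colour-change
coordination feedback fires whenever the relative phase is inside the
current error bandwidth, on every trial except each fifth one.  The
bandwidth starts at ±30° and is faded in 5° steps down to ±10°: a session
earns a step when PTT20 exceeds 0.5 on at least 20 of its 30 trials.
Training stops once the bandwidth has reached ±10° and the last two
sessions each had at least 20 trials with PTT20 above 0.6, or after 10
sessions, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, ProtocolError
from .kinematics import PhaseSeries, folded_distance, score_trial
from .synthetic import OscillatorParams, SkillState, simulate_movement_trial

__all__ = [
    "BANDWIDTH_SCHEDULE",
    "ProgressionState",
    "FeedbackSignal",
    "feedback_signal",
    "feedback_schedule",
    "kr_comment",
    "progression_update",
    "run_virtual_training",
]

#: Feedback bandwidths in fading order, degrees.
BANDWIDTH_SCHEDULE = (30.0, 25.0, 20.0, 15.0, 10.0)

TRIALS_PER_SESSION = 30
MAX_SESSIONS = 10
PROGRESSION_PTT = 0.5  # strict: score must exceed this
PROGRESSION_COUNT = 20
STOP_PTT = 0.6  # strict
STOP_COUNT = 20

_KR_COMMENTS = (
    (25.0, "This is still a little low—keep trying!"),
    (50.0, "Definitely improving—keep it up!"),
    (75.0, "Doing great—keep it up!"),
    (100.0, "This is really great—great job!"),
)


@dataclass(frozen=True)
class FeedbackSignal:
    """Per-sample boolean: whether the colour-change feedback is on."""

    on: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "on", np.asarray(self.on, dtype=bool))


@dataclass(frozen=True)
class ProgressionState:
    """State of one participant's progression through training."""

    bandwidth: float = BANDWIDTH_SCHEDULE[0]
    session_count: int = 0
    history: tuple[tuple[float, ...], ...] = ()
    stopped: bool = False
    stop_reason: str = "none"  # none | criterion_met | max_sessions

    def __post_init__(self) -> None:
        if self.bandwidth not in BANDWIDTH_SCHEDULE:
            raise InvalidParameterError(
                f"bandwidth must be one of {BANDWIDTH_SCHEDULE}"
            )
        if self.session_count > MAX_SESSIONS:
            raise InvalidParameterError(f"session_count exceeds {MAX_SESSIONS}")


def feedback_signal(series: PhaseSeries, bandwidth: float) -> FeedbackSignal:
    """Colour feedback is on at each sample whose folded distance from the
    target is within the error bandwidth (same predicate PTT uses)."""
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    dist = folded_distance(series.relative_phase, series.target_phase)
    return FeedbackSignal(on=dist <= bandwidth)


def feedback_schedule(trial_index: int) -> bool:
    """Coordination feedback is shown on every trial except each fifth one
    (1-based indexing)."""
    if trial_index < 1:
        raise InvalidParameterError("trial_index is 1-based")
    return trial_index % 5 != 0


def kr_comment(ptt_percent: float) -> str:
    """Knowledge-of-results comment for a performance percentage.

    Buckets are half-open at the printed shared edges ([0,25), [25,50),
    [50,75)) with the top bucket closed at 100.
    """
    if not 0.0 <= ptt_percent <= 100.0:
        raise InvalidParameterError("ptt_percent must be in [0, 100]")
    for upper, comment in _KR_COMMENTS:
        if ptt_percent < upper or upper == 100.0:
            return comment
    raise AssertionError("unreachable")


def progression_update(state: ProgressionState,
                       session_scores: Sequence[float]) -> ProgressionState:
    """Apply one completed training session to the progression state.

    Fades the bandwidth by 5° (floor 10°) when more than 20 of the 30 trial
    scores strictly exceed 0.5; then stops with ``criterion_met`` when the
    bandwidth is at 10° and each of the last two sessions had at least 20
    scores strictly above 0.6, or with ``max_sessions`` at session 10.
    """
    if state.stopped:
        raise ProtocolError("participant already stopped training")
    scores = tuple(float(s) for s in session_scores)
    if len(scores) != TRIALS_PER_SESSION:
        raise ProtocolError(
            f"a training session has {TRIALS_PER_SESSION} trials, got {len(scores)}"
        )
    history = state.history + (scores,)
    session_count = state.session_count + 1

    bandwidth = state.bandwidth
    if sum(s > PROGRESSION_PTT for s in scores) >= PROGRESSION_COUNT:
        bandwidth = max(bandwidth - 5.0, BANDWIDTH_SCHEDULE[-1])

    stopped, reason = False, "none"
    if bandwidth == BANDWIDTH_SCHEDULE[-1] and len(history) >= 2:
        last_two = history[-2:]
        if all(sum(s > STOP_PTT for s in sess) >= STOP_COUNT for sess in last_two):
            stopped, reason = True, "criterion_met"
    if not stopped and session_count >= MAX_SESSIONS:
        stopped, reason = True, "max_sessions"

    return ProgressionState(bandwidth=bandwidth, session_count=session_count,
                            history=history, stopped=stopped, stop_reason=reason)


def run_virtual_training(skill_schedule: Sequence[SkillState], seed: int,
                         osc: OscillatorParams | None = None,
                         scoring_bandwidth: float = 20.0) -> dict:
    """Drive a virtual participant through training until a stop rule fires.

    ``skill_schedule`` supplies the movement dynamics for sessions 1..10 (a
    steeply improving schedule stops early on the performance criterion; a
    flat one exhausts all 10 sessions).  Returns a session-by-session log:
    feedback bandwidth, 30 trial scores, feedback flags, knowledge-of-results
    comments, progression decision, and the final state.
    """
    if len(skill_schedule) < MAX_SESSIONS:
        raise InvalidParameterError(
            f"skill_schedule must cover {MAX_SESSIONS} sessions"
        )
    osc = osc or OscillatorParams()
    rng = np.random.default_rng(seed)
    state = ProgressionState()
    sessions = []
    while not state.stopped:
        skill = skill_schedule[state.session_count].with_target(90.0)
        bandwidth_in = state.bandwidth
        scores, feedback_flags, comments = [], [], []
        for trial_idx in range(1, TRIALS_PER_SESSION + 1):
            trial = simulate_movement_trial(osc, skill, rng)
            score = score_trial(trial, bandwidth=scoring_bandwidth)
            scores.append(score.ptt)
            with_feedback = feedback_schedule(trial_idx)
            feedback_flags.append(with_feedback)
            comments.append(kr_comment(100.0 * score.ptt) if with_feedback else None)
        state = progression_update(state, scores)
        sessions.append({
            "session": state.session_count,
            "feedback_bandwidth": bandwidth_in,
            "scores": scores,
            "feedback": feedback_flags,
            "kr_comments": comments,
            "progressed": state.bandwidth < bandwidth_in,
            "stopped": state.stopped,
            "stop_reason": state.stop_reason,
        })
    return {"sessions": sessions, "final_state": state}
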