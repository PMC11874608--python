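"""Synthetic movement trials, virtual study datasets, and a simulated 2AFC observer.

The movement generator produces the kind of data a bimanual coordination
experiment records: two joystick position traces sampled at 60 Hz for 20 s,
whose relative phase is governed by a stochastic differential equation with
an HKB-style intrinsic potential (attractors at 0° and 180°, with 0° the
deeper of the two and 90° unstable) plus a learned attraction toward the
task's target phase.  A single ``coupling_strength`` knob plays the role of
skill: raising it deepens the attractor at the target phase, so scored
performance improves.

The observer model is a standard two-alternative forced-choice (2AFC)
psychometric observer: probability correct rises from chance (0.5) with the
absolute difference of the comparison phase from the 90° standard,
following a Weibull function parameterised directly by its 70.71 %-correct
point — the convergence point of a transformed 1-up/2-down staircase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError, UndefinedPhaseError

__all__ = [
    "OscillatorParams",
    "SkillState",
    "TrialTimeSeries",
    "ObserverModel",
    "SessionSpec",
    "ParticipantRecord",
    "StudyDataset",
    "default_design",
    "simulate_movement_trial",
    "simulate_study",
    "observer_respond",
    "probability_correct",
    "relative_position_variable",
]

#: Assessment target phases, in the order blocks are run.
ASSESSMENT_PHASES = (0.0, 180.0, 90.0, 30.0, 60.0, 120.0, 150.0)

# Convergence point of a transformed 1-up/2-down staircase: sqrt(0.5).
_P_CONVERGENCE = math.sqrt(0.5)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class OscillatorParams:
    """Kinematic parameters of one on-screen dot oscillation.

    Defaults match the display conditions of the task being emulated:
    1 Hz movement, 300-pixel amplitude, 60 Hz sampling, 20-s trials.
    """

    frequency: float = 1.0  # cycles/s
    amplitude: float = 300.0  # screen units (pixels)
    sample_rate: float = 60.0  # samples/s
    duration: float = 20.0  # s

    def __post_init__(self) -> None:
        for name in ("frequency", "amplitude", "sample_rate", "duration"):
            _require_finite(name, getattr(self, name))
        if self.frequency <= 0 or self.amplitude <= 0 or self.duration <= 0:
            raise InvalidParameterError(
                "frequency, amplitude and duration must be positive"
            )
        if self.sample_rate < 4 * self.frequency:
            raise InvalidParameterError(
                f"sample_rate ({self.sample_rate}) must be at least 4x "
                f"frequency ({self.frequency})"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi * self.frequency

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class SkillState:
    """Parameters of the relative-phase dynamics for one virtual performer.

    ``intrinsic_a`` and ``intrinsic_b`` set the depths of the 0° and 180°
    attractors of the intrinsic coordination potential
    ``V(phi) = -a cos(phi) - b cos(2 phi)``; with both positive and
    ``b/a > 1/4`` the dynamics have stable fixed points at 0° and 180° only,
    with 0° the deeper attractor and 90° a repeller.  ``coupling_strength``
    adds a learned attraction toward ``target_phase``; it is the single
    skill knob a training schedule raises.  ``noise_sd`` is the diffusion
    of the phase SDE in degrees per sqrt(second).
    """

    target_phase: float  # degrees
    coupling_strength: float = 0.0
    intrinsic_a: float = 0.5
    intrinsic_b: float = 0.5
    noise_sd: float = 25.0  # degrees / sqrt(s)

    def __post_init__(self) -> None:
        for name in (
            "target_phase",
            "coupling_strength",
            "intrinsic_a",
            "intrinsic_b",
            "noise_sd",
        ):
            _require_finite(name, getattr(self, name))
        if self.intrinsic_a <= 0:
            raise InvalidParameterError("intrinsic_a must be > 0")
        if self.intrinsic_b < 0:
            raise InvalidParameterError("intrinsic_b must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.coupling_strength < 0:
            raise InvalidParameterError("coupling_strength must be >= 0")

    def with_target(self, target_phase: float) -> "SkillState":
        return replace(self, target_phase=float(target_phase))


@dataclass(frozen=True)
class TrialTimeSeries:
    """Raw two-channel position trace for one trial.

    ``left_position`` drives the top dot, ``right_position`` the bottom dot.
    """

    time: np.ndarray  # s, constant step
    left_position: np.ndarray  # screen units
    right_position: np.ndarray  # screen units
    target_phase: float  # degrees
    session_index: int = 1
    trial_index: int = 1

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        left = np.asarray(self.left_position, dtype=float)
        right = np.asarray(self.right_position, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "left_position", left)
        object.__setattr__(self, "right_position", right)
        if not (time.shape == left.shape == right.shape) or time.ndim != 1:
            raise InvalidParameterError("time and positions must be equal-length 1-D")
        if time.size < 2:
            raise InvalidParameterError("a trial needs at least two samples")
        steps = np.diff(time)
        # tolerance admits timestamps rounded to microseconds in CSV round-trips
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-3):
            raise InvalidParameterError("time must strictly increase at a constant step")
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise InvalidParameterError("positions must be finite")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class ObserverModel:
    """Parametric 2AFC observer judging which display shows the 90° standard.

    ``threshold_70`` is the absolute difference from 90° (degrees) at which
    probability correct equals sqrt(0.5) ~ 0.7071 when ``lapse_rate`` is 0;
    the underlying function is a cumulative Weibull with shape ``slope``.
    """

    threshold_70: float  # degrees
    slope: float = 3.5
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("threshold_70", "slope", "lapse_rate"):
            _require_finite(name, getattr(self, name))
        if self.threshold_70 <= 0:
            raise InvalidParameterError("threshold_70 must be > 0")
        if self.slope <= 0:
            raise InvalidParameterError("slope must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise InvalidParameterError("lapse_rate must be in [0, 0.1]")


@dataclass(frozen=True)
class SessionSpec:
    """One session of the study design: which phases, how many trials each."""

    label: str
    kind: str  # "assessment" | "training"
    phases: tuple[float, ...]
    trials_per_phase: int

    def __post_init__(self) -> None:
        if self.kind not in ("assessment", "training"):
            raise InvalidParameterError(f"unknown session kind {self.kind!r}")
        if self.trials_per_phase < 1 or not self.phases:
            raise InvalidParameterError("a session needs phases and >= 1 trial each")


@dataclass
class ParticipantRecord:
    """All simulated trials and the generating skill trajectory for one participant."""

    participant_id: str
    age_group: str
    sessions: list[dict]  # each: {"label", "kind", "trials": {phase: [TrialTimeSeries]}}
    skill_trajectory: list[SkillState]


@dataclass
class StudyDataset:
    design: list[SessionSpec]
    participants: list[ParticipantRecord]


def default_design(n_training: int = 10, assessment_trials: int = 5,
                   training_trials: int = 30) -> list[SessionSpec]:
    """Multi-session design: Baseline, n training sessions at 90°, Post-training,
    Retention.  Assessment sessions run ``assessment_trials`` trials at each of
    the seven target phases 0°-180° in 30° steps; training sessions run
    ``training_trials`` trials at 90°."""
    design = [SessionSpec("Baseline", "assessment", ASSESSMENT_PHASES, assessment_trials)]
    for i in range(1, n_training + 1):
        design.append(SessionSpec(f"Training {i}", "training", (90.0,), training_trials))
    design.append(SessionSpec("Post-training", "assessment", ASSESSMENT_PHASES,
                              assessment_trials))
    design.append(SessionSpec("Retention", "assessment", ASSESSMENT_PHASES,
                              assessment_trials))
    return design


def simulate_movement_trial(osc: OscillatorParams, skill: SkillState,
                            seed: int | np.random.Generator) -> TrialTimeSeries:
    """Simulate one bimanual trial.

    The left channel is a clean sinusoid ``A sin(omega t)``; the right channel
    is ``A sin(omega t + phi(t))`` where the relative phase ``phi`` (degrees)
    follows the Euler-Maruyama discretisation of

        dphi = [-a sin(phi) - 2 b sin(2 phi)
                + c sin(target - phi)] * (180/pi) dt + noise_sd dW

    with the trigonometric terms evaluated in radians.  ``phi(0)`` starts on
    target.  A fixed integer seed makes the trial bit-reproducible.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = osc.n_samples
    dt = 1.0 / osc.sample_rate
    t = osc.time_grid()

    a, b, c = skill.intrinsic_a, skill.intrinsic_b, skill.coupling_strength
    target_rad = math.radians(skill.target_phase)
    deg_per_rad = 180.0 / math.pi
    sqrt_dt_noise = math.sqrt(dt) * skill.noise_sd

    eps = rng.standard_normal(n - 1) if skill.noise_sd > 0 else np.zeros(n - 1)
    phi = np.empty(n)
    phi[0] = skill.target_phase
    p = math.radians(phi[0])
    for i in range(1, n):
        drift = (-a * math.sin(p) - 2.0 * b * math.sin(2.0 * p)
                 + c * math.sin(target_rad - p))
        phi[i] = phi[i - 1] + dt * drift * deg_per_rad + sqrt_dt_noise * eps[i - 1]
        p = math.radians(phi[i])

    base = osc.omega * t
    left = osc.amplitude * np.sin(base)
    right = osc.amplitude * np.sin(base + np.radians(phi))
    return TrialTimeSeries(time=t, left_position=left, right_position=right,
                           target_phase=skill.target_phase)


def simulate_study(design: Sequence[SessionSpec],
                   skill_schedule: Mapping[str, Sequence[SkillState]],
                   seed: int,
                   participants_per_group: Mapping[str, int] | None = None,
                   osc: OscillatorParams | None = None) -> StudyDataset:
    """Simulate a full multi-session study with ground truth attached.

    ``skill_schedule`` maps each age-group label to one SkillState per session
    (same length as ``design``); the skill's ``target_phase`` field is
    overridden per trial by the phase being assessed or trained, so
    ``coupling_strength`` acts on whichever target the trial demands.
    """
    design = list(design)
    if not design:
        raise InvalidParameterError("design must list at least one session")
    if participants_per_group is None:
        participants_per_group = {group: 1 for group in skill_schedule}
    osc = osc or OscillatorParams()

    for group, states in skill_schedule.items():
        if len(states) != len(design):
            raise InvalidParameterError(
                f"skill_schedule[{group!r}] has {len(states)} states for "
                f"{len(design)} sessions"
            )

    root = np.random.SeedSequence(seed)
    participants: list[ParticipantRecord] = []
    for group in sorted(skill_schedule):
        states = list(skill_schedule[group])
        for p_idx in range(participants_per_group.get(group, 0)):
            p_seq = root.spawn(1)[0]
            rng = np.random.default_rng(p_seq)
            sessions = []
            for s_idx, spec in enumerate(design):
                skill = states[s_idx]
                trials: dict[float, list[TrialTimeSeries]] = {}
                for phase in spec.phases:
                    phase_trials = []
                    for k in range(spec.trials_per_phase):
                        trial = simulate_movement_trial(osc, skill.with_target(phase), rng)
                        phase_trials.append(replace(trial, session_index=s_idx + 1,
                                                    trial_index=k + 1))
                    trials[phase] = phase_trials
                sessions.append({"label": spec.label, "kind": spec.kind,
                                 "trials": trials})
            participants.append(ParticipantRecord(
                participant_id=f"{group}{p_idx + 1:02d}", age_group=group,
                sessions=sessions, skill_trajectory=states))
    return StudyDataset(design=design, participants=participants)


def probability_correct(obs: ObserverModel, comparison_delta: float) -> float:
    """P(correct) for a 2AFC trial whose comparison differs from 90° by
    ``comparison_delta`` degrees (absolute).

    ``P(d) = 0.5 + (0.5 - lapse) * F(d)`` with ``F`` a cumulative Weibull
    scaled so that ``P(threshold_70) = sqrt(0.5)`` at zero lapse.
    """
    d = float(comparison_delta)
    if d < 0 or not math.isfinite(d):
        raise InvalidParameterError("comparison_delta must be finite and >= 0")
    # Solve F(threshold_70) = (sqrt(0.5) - 0.5) / 0.5 for the Weibull scale.
    f_at_threshold = (_P_CONVERGENCE - 0.5) / 0.5
    scale = obs.threshold_70 / (-math.log1p(-f_at_threshold)) ** (1.0 / obs.slope)
    f = 1.0 - math.exp(-((d / scale) ** obs.slope))
    return 0.5 + (0.5 - obs.lapse_rate) * f


def observer_respond(obs: ObserverModel, comparison_delta: float,
                     rng: int | np.random.Generator) -> bool:
    """Draw one simulated 2AFC response; True = correct."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return bool(rng.random() < probability_correct(obs, comparison_delta))


def relative_position_variable(x, v):
    """Relative-position information variable ``cos(theta) = x / sqrt(v^2 + x^2)``.

    ``x`` and ``v`` are position and velocity pre-normalised to a unit-amplitude,
    unit-angular-frequency oscillator, so the result lies in [-1, 1] and equals
    the cosine of the oscillator's phase angle.  Accepts scalars or arrays;
    raises if position and velocity are both zero anywhere (phase undefined).
    """
    x_arr = np.asarray(x, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    denom_sq = v_arr ** 2 + x_arr ** 2
    if np.any(denom_sq == 0):
        raise UndefinedPhaseError("position and velocity both zero: phase undefined")
    out = x_arr / np.sqrt(denom_sq)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out
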