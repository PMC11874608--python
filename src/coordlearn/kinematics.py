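"""Relative-phase scoring of bimanual position traces.

Pipeline: centre and low-pass filter each channel (2nd-order Butterworth,
10 Hz cut-off, zero-phase), differentiate to velocity, convert each channel
to a continuous phase angle via the four-quadrant arctangent of normalised
(position, velocity), take the per-sample difference, fold to [0, 180]
degrees, and score the proportion of samples within a bandwidth of the
target relative phase (PTT20 at the default 20° bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateTrialError, InvalidParameterError
from .synthetic import TrialTimeSeries

__all__ = [
    "FilteredTrajectory",
    "PhaseSeries",
    "TrialScore",
    "preprocess_trajectory",
    "continuous_phase",
    "relative_phase_series",
    "folded_distance",
    "ptt",
    "score_trial",
]


@dataclass(frozen=True)
class FilteredTrajectory:
    """Centred, filtered position and its time derivative for one channel."""

    position: np.ndarray  # screen units, mean-centred
    velocity: np.ndarray  # screen units / s
    sample_rate: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "velocity", vel)
        if pos.shape != vel.shape or pos.ndim != 1:
            raise InvalidParameterError("position/velocity must be equal-length 1-D")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
            raise InvalidParameterError("trajectory values must be finite")


@dataclass(frozen=True)
class PhaseSeries:
    """Per-sample relative phase in degrees, folded to [0, 180]."""

    relative_phase: np.ndarray
    sample_rate: float
    target_phase: float

    def __post_init__(self) -> None:
        rp = np.asarray(self.relative_phase, dtype=float)
        object.__setattr__(self, "relative_phase", rp)
        if rp.size < 2:
            raise InvalidParameterError("phase series needs at least two samples")
        if np.any(rp < 0) or np.any(rp > 180):
            raise InvalidParameterError("folded relative phase must lie in [0, 180]")


@dataclass(frozen=True)
class TrialScore:
    """Proportion of time on target: fraction of samples within ``bandwidth``
    degrees of ``target_phase`` on the folded scale."""

    ptt: float
    bandwidth: float = 20.0
    target_phase: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ptt <= 1.0:
            raise InvalidParameterError("ptt must be in [0, 1]")
        if self.bandwidth <= 0:
            raise InvalidParameterError("bandwidth must be > 0")


def preprocess_trajectory(raw_position, sample_rate: float,
                          cutoff: float = 10.0) -> FilteredTrajectory:
    """Centre, low-pass filter, and differentiate one position channel.

    The filter is a 2nd-order Butterworth applied forward-backward
    (zero-phase, so the phase estimate downstream is undistorted) with
    reflective edge padding; velocity comes from central differences.
    Requires at least 1 s of data and ``cutoff`` below the Nyquist rate.
    """
    x = np.asarray(raw_position, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("raw_position must be 1-D")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("raw_position must be finite")
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be > 0")
    if x.size < sample_rate:
        raise InvalidParameterError("need at least 1 s of data")
    if cutoff >= sample_rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below Nyquist ({sample_rate / 2} Hz)"
        )
    centred = x - x.mean()
    sos = signal.butter(2, cutoff, btype="low", fs=sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, centred, padtype="odd")
    velocity = np.gradient(filtered, 1.0 / sample_rate)
    return FilteredTrajectory(position=filtered, velocity=velocity,
                              sample_rate=sample_rate)


def _dominant_frequency(position: np.ndarray, sample_rate: float,
                        fallback: float) -> float:
    """Frequency of the largest non-DC spectral peak, or ``fallback``."""
    spectrum = np.abs(np.fft.rfft(position))
    freqs = np.fft.rfftfreq(position.size, d=1.0 / sample_rate)
    spectrum[0] = 0.0  # ignore any residual DC
    if spectrum.max() <= 0:
        return fallback
    peak = freqs[int(np.argmax(spectrum))]
    return peak if peak > 0 else fallback


def continuous_phase(traj: FilteredTrajectory, frequency_hint: float = 1.0,
                     min_amplitude: float | None = None) -> np.ndarray:
    """Unwrapped per-sample phase angle of one channel, in degrees.

    Position is normalised by the trial amplitude (half peak-to-peak) and
    velocity by amplitude x 2 pi x estimated frequency (dominant spectral
    peak, falling back to ``frequency_hint``), so for ``x = A sin(2 pi f t + c)``
    the four-quadrant arctangent of (position, velocity) recovers
    ``2 pi f t + c`` exactly, up to unwrapping.

    ``min_amplitude`` lets callers who know the nominal movement amplitude
    reject degenerate trials (e.g. 1 % of the screen amplitude); without it
    only numerically-zero amplitudes are rejected.
    """
    pos = traj.position
    amplitude = 0.5 * (pos.max() - pos.min())
    floor = max(1e-9, min_amplitude or 0.0)
    if amplitude < floor:
        raise DegenerateTrialError("oscillation amplitude too small to estimate phase")
    freq = _dominant_frequency(pos, traj.sample_rate, frequency_hint)
    x_norm = pos / amplitude
    v_norm = traj.velocity / (amplitude * 2.0 * np.pi * freq)
    phase = np.unwrap(np.arctan2(x_norm, v_norm))
    return np.degrees(phase)


def relative_phase_series(left, right, target_phase: float,
                          sample_rate: float = 60.0) -> PhaseSeries:
    """Per-sample left-minus-right phase difference, wrapped to (-180, 180]
    and folded by absolute value to [0, 180] (lead and lag pooled)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise InvalidParameterError("left and right phase series differ in length")
    diff = left - right
    wrapped = np.mod(diff + 180.0, 360.0) - 180.0
    folded = np.abs(wrapped)
    return PhaseSeries(relative_phase=folded, sample_rate=sample_rate,
                       target_phase=float(target_phase))


def folded_distance(phase, target_phase: float) -> np.ndarray:
    """Circular distance between folded phases.

    A folded value ``s`` stands for the pair {s, -s} on the circle, so the
    distance to the (folded) target is the minimum over the three candidate
    arcs ``|s - t|``, ``s + t`` and ``360 - s - t``.
    """
    s = np.asarray(phase, dtype=float)
    t = float(target_phase)
    return np.minimum.reduce([np.abs(s - t), s + t, 360.0 - s - t])


def ptt(series: PhaseSeries, bandwidth: float = 20.0) -> TrialScore:
    """Proportion of samples within ``bandwidth`` degrees of the target
    (closed band: distance <= bandwidth counts as on target)."""
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    dist = folded_distance(series.relative_phase, series.target_phase)
    proportion = float(np.mean(dist <= bandwidth))
    return TrialScore(ptt=proportion, bandwidth=bandwidth,
                      target_phase=series.target_phase)


def score_trial(trial: TrialTimeSeries, bandwidth: float = 20.0,
                cutoff: float = 10.0, frequency_hint: float = 1.0,
                trim: float = 0.0) -> TrialScore:
    """Score a raw trial end to end: filter both channels, extract phases,
    difference and fold, then count time on target.

    ``trim`` discards that many seconds from each end of the phase series
    before scoring (default: none).
    """
    sr = trial.sample_rate
    left = continuous_phase(preprocess_trajectory(trial.left_position, sr, cutoff),
                            frequency_hint)
    right = continuous_phase(preprocess_trajectory(trial.right_position, sr, cutoff),
                             frequency_hint)
    series = relative_phase_series(left, right, trial.target_phase, sample_rate=sr)
    if trim > 0:
        k = int(round(trim * sr))
        if 2 * k >= series.relative_phase.size - 1:
            raise InvalidParameterError("trim removes the whole trial")
        series = PhaseSeries(series.relative_phase[k:series.relative_phase.size - k],
                             sr, series.target_phase)
    return ptt(series, bandwidth)
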