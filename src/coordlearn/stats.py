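"""Statistical layer: planned contrasts for transfer of learning, multiplicity
control, proportion-of-transfer, and exponential learning-curve fitting.

The central test is a dependent-measures contrast analysis.  Each
participant's session means ``x_ij`` are collapsed with zero-sum weights
``lambda_j`` into a single score ``L_i = sum_j x_ij lambda_j``; under the
null hypothesis that the sessions do not differ in the hypothesised pattern,
the ``L_i`` are centred on zero, and

    t = L_bar / sqrt(s_L^2 / n)

is referred to the t distribution with n - 1 degrees of freedom.  The
standardised effect size is g = L_bar / s_L = t / sqrt(n).

Group learning curves are summarised by fitting ``PTT20 = a exp(-b / S)``
to the mean 90° performance per session S, and the learning rate is the
analytic derivative ``(a b / S^2) exp(-b / S)`` evaluated at S = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateVarianceError, FitFailureError, InvalidParameterError

__all__ = [
    "ContrastResult",
    "LearningFit",
    "TransferReport",
    "contrast_test",
    "lambda_weights",
    "holm_bonferroni",
    "proportion_of_transfer",
    "fit_learning_curve",
    "learning_rate",
]

#: Named contrast-weight patterns over (Baseline, Post-training, Retention).
#: Action patterns encode "improve then (partially) retain"; judgement
#: patterns are sign-flipped because lower thresholds mean improvement.
_LAMBDA_PATTERNS: dict[str, tuple[float, ...]] = {
    "ya_action": (-3.0, 2.0, 1.0),
    "oa_action": (-2.0, 1.0, 1.0),
    "ya_judgement": (3.0, -2.0, -1.0),
    "oa_judgement": (2.0, -1.0, -1.0),
}


@dataclass(frozen=True)
class ContrastResult:
    L_scores: np.ndarray  # per-participant contrast values
    L_mean: float
    L_var: float  # sample variance, n-1 denominator
    n: int
    t: float
    df: int
    p: float  # two-sided
    g: float  # L_mean / sd(L) = t / sqrt(n)
    lambdas: tuple[float, ...]


@dataclass(frozen=True)
class LearningFit:
    a: float  # asymptote-scale parameter
    b: float  # decay parameter
    r_squared: float
    session_means: np.ndarray
    session_index: np.ndarray
    learning_rate_S1: float  # a * b * exp(-b)


@dataclass(frozen=True)
class TransferReport:
    proportions: dict[float, float]  # phase -> signed fraction of transfer
    criterion_phase: float


def contrast_test(data, lambdas: Sequence[float]) -> ContrastResult:
    """Dependent-measures contrast: one-sample t test on the per-participant
    weighted session sums.

    ``data`` is participants x sessions (array or DataFrame); ``lambdas``
    must sum to zero with one weight per session column.
    """
    x = np.asarray(data, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if x.ndim != 2:
        raise InvalidParameterError("data must be a participants x sessions table")
    if lam.ndim != 1 or lam.size != x.shape[1]:
        raise InvalidParameterError("one lambda weight per session column required")
    if abs(lam.sum()) > 1e-9:
        raise InvalidParameterError(f"lambda weights must sum to 0, got {lam.sum()}")
    if x.shape[0] < 2:
        raise InvalidParameterError("need at least 2 participants")
    if np.any(~np.isfinite(x)):
        raise InvalidParameterError("data contains missing or non-finite cells")

    L = x @ lam
    n = L.size
    L_mean = float(L.mean())
    L_var = float(L.var(ddof=1))
    if L_var == 0.0:
        raise DegenerateVarianceError("contrast variance is zero; t undefined")
    t = L_mean / math.sqrt(L_var / n)
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    g = t / math.sqrt(n)
    return ContrastResult(L_scores=L, L_mean=L_mean, L_var=L_var, n=n, t=t,
                          df=df, p=p, g=g, lambdas=tuple(lam))


def lambda_weights(pattern: str) -> tuple[float, ...]:
    """Named zero-sum weight patterns over (Baseline, Post-training, Retention)."""
    try:
        return _LAMBDA_PATTERNS[pattern]
    except KeyError:
        raise InvalidParameterError(
            f"unknown pattern {pattern!r}; choose from {sorted(_LAMBDA_PATTERNS)}"
        ) from None


def holm_bonferroni(p_values: Mapping, alpha: float = 0.05) -> dict:
    """Holm-Bonferroni step-down correction over a family of tests.

    Returns a mapping from each key to the reject/accept decision at
    family-wise level ``alpha``.
    """
    keys = list(p_values)
    pvals = [float(p_values[k]) for k in keys]
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise InvalidParameterError("p values must lie in [0, 1]")
    if not keys:
        return {}
    reject, *_ = multipletests(pvals, alpha=alpha, method="holm")
    return {k: bool(r) for k, r in zip(keys, reject)}


def proportion_of_transfer(baseline: Mapping[float, float],
                           post: Mapping[float, float],
                           criterion_phase: float) -> TransferReport:
    """Change at each phase as a signed fraction of the change at the trained
    (criterion) phase: (post - baseline at phase) / (post - baseline at
    criterion).  The criterion phase itself maps to 1 by construction."""
    if criterion_phase not in baseline or criterion_phase not in post:
        raise InvalidParameterError("criterion phase missing from the means")
    denom = post[criterion_phase] - baseline[criterion_phase]
    if denom == 0:
        raise InvalidParameterError("criterion phase shows zero change")
    proportions = {
        float(phase): (post[phase] - baseline[phase]) / denom
        for phase in baseline
        if phase in post
    }
    return TransferReport(proportions=proportions,
                          criterion_phase=float(criterion_phase))


def _exp_curve(S, a, b):
    return a * np.exp(-b / S)


def learning_rate(a: float, b: float, S: float = 1.0) -> float:
    """Derivative of ``a exp(-b / S)`` with respect to session:
    ``(a b / S^2) exp(-b / S)``; at S = 1 this is the learning rate."""
    if S <= 0:
        raise InvalidParameterError("session index S must be > 0")
    return (a * b) / S ** 2 * math.exp(-b / S)


def fit_learning_curve(session_means: Sequence[float],
                       session_index: Sequence[int] | None = None) -> LearningFit:
    """Nonlinear least-squares fit of ``a exp(-b / S)`` to per-session means.

    Sessions are numbered consecutively from 1 (Baseline) unless an explicit
    index is given.  Initialised at ``a = max(session_means), b = 1`` with
    bounds a in [0, 1.5], b in [0, 20]; the learning rate is the analytic
    derivative at S = 1.
    """
    y = np.asarray(session_means, dtype=float)
    if y.size < 3:
        raise InvalidParameterError("need at least 3 sessions to fit")
    if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y > 1):
        raise InvalidParameterError("session means must be finite proportions")
    if session_index is None:
        S = np.arange(1, y.size + 1, dtype=float)
    else:
        S = np.asarray(session_index, dtype=float)
        if S.shape != y.shape or np.any(S <= 0):
            raise InvalidParameterError("session_index must be positive, one per mean")

    try:
        popt, _ = optimize.curve_fit(
            _exp_curve, S, y, p0=[max(float(y.max()), 1e-3), 1.0],
            bounds=([0.0, 0.0], [1.5, 20.0]), maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"learning-curve fit failed: {exc}") from exc
    a, b = (float(v) for v in popt)
    resid = y - _exp_curve(S, a, b)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r_squared = 1.0 if ss_res < 1e-12 else -math.inf
    else:
        r_squared = 1.0 - ss_res / ss_tot
    return LearningFit(a=a, b=b, r_squared=r_squared, session_means=y,
                       session_index=S, learning_rate_S1=learning_rate(a, b, 1.0))
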