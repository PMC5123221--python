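"""Closed-form signal-detection mathematics on the bivariate-normal model.

True severity Y and perceived severity X are standard bivariate normal
with correlation rho.  A patient has a disorder when Y exceeds the
prevalence cutoff c = Phi^-1(1 - prevalence); a patient is referred when
X meets or exceeds the decision threshold t.  Everything here follows in
closed form (orthant probabilities of the bivariate normal and the
conditional distribution of Y given X), making this module both the
production code for threshold-probability axes and Youden operating
points, and a deterministic oracle for validating the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import sqrt

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm

__all__ = [
    "OperatingPoint",
    "severity_cutoff",
    "static_sensitivity",
    "static_specificity",
    "youden_threshold",
    "threshold_probability",
    "threshold_for_probability",
    "equal_error_threshold",
    "equal_error_weight",
    "screen_positive_rate",
    "operating_table",
    "DegenerateROCError",
]


class DegenerateROCError(ValueError):
    """The ROC curve is degenerate (rho = 0 or rho = 1 where disallowed)."""


@dataclass(frozen=True)
class OperatingPoint:
    """A decision threshold with its static operating characteristics."""

    threshold: float
    sensitivity: float
    specificity: float
    threshold_probability: float


@lru_cache(maxsize=1024)
def severity_cutoff(prevalence: float) -> float:
    """Severity value whose upper-tail probability equals ``prevalence``.

    Patients with true severity above this cutoff (the extreme
    ``prevalence`` fraction of the population) are classified as having
    a disorder.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    return float(norm.isf(prevalence))


@lru_cache(maxsize=256)
def _bvn(rho: float):
    return multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])


def _lower_orthant(t: float, c: float, rho: float) -> float:
    """P(X < t, Y <= c) for standard bivariate normal with correlation rho."""
    if rho >= 1.0:
        # X == Y almost surely
        return float(norm.cdf(min(t, c)))
    if rho <= 0.0:
        return float(norm.cdf(t) * norm.cdf(c))
    return float(_bvn(round(rho, 12)).cdf(np.array([t, c])))


def static_sensitivity(threshold: float, rho: float, prevalence: float) -> float:
    """P(perceived >= threshold | true > cutoff): referral rate among diseased.

    Computed from the upper-orthant probability of the bivariate normal,
    P(X >= t, Y > c) / prevalence.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    c = severity_cutoff(prevalence)
    upper = 1.0 - norm.cdf(threshold) - norm.cdf(c) + _lower_orthant(threshold, c, rho)
    return float(min(1.0, max(0.0, upper / prevalence)))


def static_specificity(threshold: float, rho: float, prevalence: float) -> float:
    """P(perceived < threshold | true <= cutoff): non-referral among healthy."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    c = severity_cutoff(prevalence)
    return float(min(1.0, max(0.0, _lower_orthant(threshold, c, rho) / (1.0 - prevalence))))


def threshold_probability(threshold: float, rho: float, prevalence: float) -> float:
    """P(disorder | perceived severity = threshold).

    The conditional law of true severity given perceived severity t is
    N(rho*t, 1 - rho^2); the threshold probability is its upper-tail mass
    beyond the prevalence cutoff.  This is the probability that a patient
    scoring exactly at the decision threshold truly has a disorder -- the
    natural clinical scale on which to read a threshold.
    """
    if not 0.0 <= rho < 1.0:
        raise DegenerateROCError(
            f"rho must lie in [0, 1) for a conditional distribution, got {rho}"
        )
    c = severity_cutoff(prevalence)
    sigma = sqrt(1.0 - rho * rho)
    return float(norm.sf((c - rho * threshold) / sigma))


def threshold_for_probability(p: float, rho: float, prevalence: float) -> float:
    """Inverse of :func:`threshold_probability` in the threshold argument."""
    if not 0.0 < rho < 1.0:
        raise DegenerateROCError("rho must lie in (0, 1) to invert")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    c = severity_cutoff(prevalence)
    sigma = sqrt(1.0 - rho * rho)
    return float((c - sigma * norm.isf(p)) / rho)


def _operating_point(threshold: float, rho: float, prevalence: float) -> OperatingPoint:
    return OperatingPoint(
        threshold=float(threshold),
        sensitivity=static_sensitivity(threshold, rho, prevalence),
        specificity=static_specificity(threshold, rho, prevalence),
        threshold_probability=(
            threshold_probability(threshold, rho, prevalence) if rho < 1.0 else 1.0
        ),
    )


@lru_cache(maxsize=256)
def youden_threshold(rho: float, prevalence: float) -> OperatingPoint:
    """Threshold maximizing Youden's index (sensitivity + specificity - 1).

    This is the conventional cut score of a screening instrument.  For
    rho = 0 every threshold has the same Youden sum (a flat, degenerate
    ROC), so no maximizer exists.
    """
    if not 0.0 < rho <= 1.0:
        raise DegenerateROCError("Youden threshold undefined for rho = 0")
    if rho >= 1.0:
        c = severity_cutoff(prevalence)
        return OperatingPoint(c, 1.0, 1.0, 1.0)

    def neg_youden(t: float) -> float:
        return -(static_sensitivity(t, rho, prevalence)
                 + static_specificity(t, rho, prevalence))

    res = optimize.minimize_scalar(neg_youden, bounds=(-4.0, 4.0), method="bounded",
                                   options={"xatol": 1e-8})
    return _operating_point(res.x, rho, prevalence)


def equal_error_threshold(rho: float, prevalence: float) -> float:
    """Threshold at which static sensitivity equals static specificity."""
    if not 0.0 < rho < 1.0:
        raise DegenerateROCError("equal-error threshold requires rho in (0, 1)")

    def gap(t: float) -> float:
        return (static_sensitivity(t, rho, prevalence)
                - static_specificity(t, rho, prevalence))

    return float(optimize.brentq(gap, -4.0, 4.0, xtol=1e-10))


def equal_error_weight(rho: float, prevalence: float) -> float:
    """FN regret weight whose indifference point is the equal-error threshold.

    Regret theory places a physician's decision threshold at the severity
    where the threshold probability p satisfies p / (1 - p) = 1 / w, i.e.
    w = (1 - p) / p.  Evaluating p at the equal-error threshold yields the
    weight that should drive the model to equal sensitivity and
    specificity.
    """
    t_ee = equal_error_threshold(rho, prevalence)
    p = threshold_probability(t_ee, rho, prevalence)
    if p <= 0.0:
        raise ValueError("degenerate threshold probability at the equal-error point")
    return float((1.0 - p) / p)


def screen_positive_rate(rho: float = 0.85, prevalence: float = 0.15) -> float:
    """Population fraction scoring at/above the Youden threshold for ``rho``.

    By total probability this equals
    prevalence * sens_Y + (1 - prevalence) * (1 - spec_Y)
    at the Youden operating point -- the fraction of children a screening
    instrument of accuracy ``rho`` would flag positive.
    """
    op = youden_threshold(rho, prevalence)
    return float(norm.sf(op.threshold))


def operating_table(rho: float, prevalence: float,
                    thresholds=None) -> "pandas.DataFrame":
    """Tabulate operating points over a range of thresholds (for the CLI)."""
    import pandas as pd

    if thresholds is None:
        thresholds = np.linspace(-3.0, 3.0, 61)
    rows = [_operating_point(float(t), rho, prevalence) for t in thresholds]
    return pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
            "specificity": [r.specificity for r in rows],
            "threshold_probability": [r.threshold_probability for r in rows],
        }
    )
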