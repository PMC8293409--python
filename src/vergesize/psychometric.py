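"""Four-parameter logistic psychometric function and size-constancy predictions.

The observer model underlying every stage of the pipeline: the probability
of responding "bigger" to a signed percentage size change ``x`` is

    P(bigger | x) = gamma + (1 - gamma - lambda) * logistic(beta * (x - alpha))

with bias ``alpha`` (the point of subjective equality, in % size change),
slope ``beta`` (per % size change, on the linear scale), floor ``gamma``
(lower asymptote) and ceiling lapse ``lambda`` (upper asymptote is
``1 - lambda``).  Positive ``x`` codes physical growth of the target, so a
vergence-micropsia compensation (size constancy) predicts a *positive*
fitted bias: the target must physically grow to null the perceived
shrinkage as the eyes converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PFParams",
    "pf_prob",
    "slope_from_threshold",
    "threshold_from_slope",
    "nulling_size_change",
    "perceived_size_change",
    "DEFAULT_CRITERION",
]

#: Lapse-free probability-correct criterion defining the "detection
#: threshold": the underlying logistic passes this value at
#: x = alpha + threshold.  0.76 is the common 2AFC convention.
DEFAULT_CRITERION = 0.76


@dataclass(frozen=True)
class PFParams:
    """Parameters of one observer's four-parameter logistic.

    Attributes
    ----------
    alpha : float
        Bias / point of subjective equality, in signed % size change.
    beta : float
        Slope per % size change on the linear scale (must be > 0).
    gamma : float
        Floor (lower asymptote), in [0, 0.5).
    lambda_ : float
        Ceiling lapse rate, in [0, 0.5); the upper asymptote is 1 - lambda_.
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not (self.beta > 0):
            raise ValueError("beta (slope) must be positive")
        for name, v in (("gamma", self.gamma), ("lambda_", self.lambda_)):
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")
        if self.gamma + self.lambda_ >= 1.0:
            raise ValueError("gamma + lambda must be < 1")

    @property
    def beta_log10(self) -> float:
        """Slope on the log10 scale, the convention used for reporting."""
        return float(np.log10(self.beta))

    def threshold(self, criterion: float = DEFAULT_CRITERION) -> float:
        """Lapse-free detection threshold at the given criterion."""
        return threshold_from_slope(self.beta, criterion)


def pf_prob(params: PFParams, x) -> np.ndarray | float:
    """Probability of responding "bigger" at signed size change(s) ``x`` (%).

    Monotone increasing in ``x``; range [gamma, 1 - lambda].
    """
    x = np.asarray(x, dtype=float)
    p = params.gamma + (1.0 - params.gamma - params.lambda_) * expit(
        params.beta * (x - params.alpha)
    )
    return float(p) if p.ndim == 0 else p


def slope_from_threshold(threshold, criterion: float = DEFAULT_CRITERION):
    """Convert a detection threshold (% size change) into a logistic slope.

    Defined so that the lapse-free logistic passes ``criterion`` at
    ``x = alpha + threshold``:  beta = ln(criterion/(1-criterion)) / threshold.
    Accepts scalars or arrays.
    """
    thr = np.asarray(threshold, dtype=float)
    if np.any(thr <= 0):
        raise ValueError("threshold must be positive")
    if not (0.5 < criterion < 1.0):
        raise ValueError("criterion must lie in (0.5, 1)")
    out = np.log(criterion / (1.0 - criterion)) / thr
    return float(out) if out.ndim == 0 else out


def threshold_from_slope(beta, criterion: float = DEFAULT_CRITERION):
    """Inverse of :func:`slope_from_threshold`; accepts scalars or arrays."""
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("beta must be positive")
    if not (0.5 < criterion < 1.0):
        raise ValueError("criterion must lie in (0.5, 1)")
    out = np.log(criterion / (1.0 - criterion)) / b
    return float(out) if out.ndim == 0 else out


def nulling_size_change(g: float, distance_ratio: float = 2.0):
    """Physical % size change that nulls perceived change under partial constancy.

    A constancy mechanism of strength ``g`` in [0, 1] rescales perceived
    angular size by ``distance_ratio ** (-g)`` when the vergence-specified
    distance shrinks by ``distance_ratio`` (start/end).  Under the
    small-angle approximation the physical growth cancelling that rescaling
    is ``(distance_ratio**g - 1) * 100`` percent: 0% with no constancy,
    +100% with full constancy for a halving of distance.
    """
    g = np.asarray(g, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("constancy fraction g must lie in [0, 1]")
    if not (distance_ratio > 0):
        raise ValueError("distance_ratio must be positive")
    out = (np.power(distance_ratio, g) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def perceived_size_change(g: float, distance_ratio: float = 2.0):
    """Perceived % size change of a fixed-retinal-size target under constancy ``g``.

    With the retinal image held fixed while the vergence-specified distance
    shrinks by ``distance_ratio``, a constancy mechanism of strength ``g``
    makes the target appear to change by ``(distance_ratio**(-g) - 1) * 100``
    percent: full constancy (g = 1) over a halving of distance yields a
    −50% perceived change.
    """
    g = np.asarray(g, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("constancy fraction g must lie in [0, 1]")
    if not (distance_ratio > 0):
        raise ValueError("distance_ratio must be positive")
    out = (np.power(distance_ratio, -g) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out
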