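"""Null-acceptance inference: JZS Bayes factor, inferiority test, and the
size-constancy prediction overlay.

A conventional non-significant t-test cannot support "vergence has no
effect on perceived size"; the two instruments here can.  The JZS Bayes
factor quantifies evidence *for* the null (BF01 > 1 favours bias = 0),
and the inferiority test asks whether any effect, if present, is smaller
than the smallest effect size of interest — the detection threshold of
the most sensitive observer, 1.43% — in the direction micropsia predicts
(positive bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .fit import credible_interval
from .psychometric import nulling_size_change

__all__ = [
    "InferiorityResult",
    "jzs_bayes_factor",
    "inferiority_test",
    "constancy_overlay",
    "DEFAULT_MARGIN_PCT",
    "DEFAULT_CAUCHY_SCALE",
]

#: Smallest effect size of interest (% size change): the detection
#: threshold of the most sensitive observer.
DEFAULT_MARGIN_PCT = 1.43

#: Default Cauchy prior scale on the standardised effect (r = sqrt(2)/2).
DEFAULT_CAUCHY_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class InferiorityResult:
    """Outcome of the directional inferiority test."""

    directional_bound: float
    margin: float
    verdict: bool
    level: float
    direction: str

    def __str__(self) -> str:
        rel = "<" if self.verdict else ">="
        word = "pass" if self.verdict else "fail"
        return (
            f"inferiority {word}: {self.direction} bound of the central "
            f"{self.level:.0%} interval = {self.directional_bound:.3g}% "
            f"{rel} margin {self.margin:.3g}%"
        )


def jzs_bayes_factor(values, cauchy_scale: float = DEFAULT_CAUCHY_SCALE):
    """One-sample JZS (Jeffreys–Zellner–Siow) Bayes factor BF01.

    Under H1 the standardised effect delta = mean/sd carries a
    Cauchy(0, ``cauchy_scale``) prior; the marginal likelihood of the
    observed t statistic is the non-central t density integrated over that
    prior, and BF01 is the central-t density at t divided by that
    marginal.  BF01 > 1 favours the null (zero bias).

    Returns ``(bf01, err)`` where ``err`` propagates the quadrature error
    estimate onto BF01.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    n = v.size
    sd = v.std(ddof=1)
    mean = v.mean()
    if sd == 0.0:
        if mean == 0.0:
            t = 0.0
        else:
            # infinitely strong evidence against the null
            return 0.0, 0.0
    else:
        t = mean / (sd / np.sqrt(n))
    df = n - 1

    def integrand(delta):
        return stats.nct.pdf(t, df, np.sqrt(n) * delta) * stats.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )

    m1, quad_err = integrate.quad(integrand, -np.inf, np.inf)
    m0 = stats.t.pdf(t, df)
    bf01 = m0 / m1
    return float(bf01), float(bf01 * quad_err / m1)


def inferiority_test(
    bias_draws,
    margin: float = DEFAULT_MARGIN_PCT,
    direction: str = "positive",
    level: float = 0.90,
) -> InferiorityResult:
    """Directional inferiority test of the population bias.

    Takes the directional bound of the central ``level`` interval of the
    posterior bias draws (or bias estimates) in the predicted direction —
    for micropsia, positive — and passes iff that bound falls short of
    ``margin``: any size-constancy effect, if present, is then smaller
    than the smallest effect size of interest.
    """
    if not (margin > 0):
        raise ValueError("margin must be positive")
    d = np.asarray(bias_draws, dtype=float).reshape(-1)
    if d.size == 0:
        raise ValueError("bias draws must be non-empty")
    bound = credible_interval(d, level=level, sided="one", direction=direction)
    if direction == "positive":
        verdict = bound < margin
    elif direction == "negative":
        verdict = bound > -margin
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return InferiorityResult(float(bound), float(margin), bool(verdict),
                             float(level), direction)


def constancy_overlay(g_values, distance_ratio: float = 2.0) -> np.ndarray:
    """Predicted nulling biases (% size change) for constancy fractions ``g``.

    Maps each g in [0, 1] to the physical size change at which an observer
    with that degree of vergence size constancy would be at chance: the
    prediction curves overlaid on the fitted psychometric function (0% for
    no constancy up to +100% for full constancy at a distance halving).
    """
    g = np.atleast_1d(np.asarray(g_values, dtype=float))
    return nulling_size_change(g, distance_ratio)
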