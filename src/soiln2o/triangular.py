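"""Triangular probability distributions for emission-factor uncertainty.

IPCC Tier 1 uncertainty propagation represents each emission factor as a
triangular distribution (lower, mode, upper).  This module provides the
closed-form moments, CDF and inverse CDF used both for sampling and as the
analytic oracle against which Monte Carlo quantiles are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriangularEF", "triangular_quantile"]


@dataclass(frozen=True)
class TriangularEF:
    """A triangular distribution over a dimensionless emission factor.

    Parameters
    ----------
    lower, mode, upper
        Distribution support and mode, ``lower <= mode <= upper``.
        A degenerate distribution (``lower == upper``) is permitted and
        behaves as a point mass at ``mode``.
    allow_negative
        Negative emission factors are physically possible (net soil uptake)
        but excluded from the packaged schemes; a negative ``lower`` must be
        requested explicitly.
    """

    lower: float
    mode: float
    upper: float
    allow_negative: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"require lower <= mode <= upper, got "
                f"({self.lower}, {self.mode}, {self.upper})"
            )
        if self.lower < 0 and not self.allow_negative:
            raise ValueError(
                "negative lower bound requires allow_negative=True"
            )

    # ------------------------------------------------------------------
    # closed forms
    # ------------------------------------------------------------------
    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0

    def var(self) -> float:
        a, c, b = self.lower, self.mode, self.upper
        return (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0

    def cdf(self, x):
        a, c, b = self.lower, self.mode, self.upper
        scalar = np.ndim(x) == 0
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        if b == a:  # point mass
            out = np.where(xa < a, 0.0, 1.0)
        else:
            out = np.zeros_like(xa)
            if c > a:
                m = (xa > a) & (xa <= c)
                out[m] = (xa[m] - a) ** 2 / ((b - a) * (c - a))
            if b > c:
                m = (xa > c) & (xa < b)
                out[m] = 1.0 - (b - xa[m]) ** 2 / ((b - a) * (b - c))
            out[xa >= b] = 1.0
        return float(out[0]) if scalar else out

    def quantile(self, p):
        """Exact inverse CDF.

        Piecewise quadratic: for ``p <= F(mode)`` the quantile is
        ``a + sqrt(p (b-a)(c-a))``, otherwise ``b - sqrt((1-p)(b-a)(b-c))``.
        """
        a, c, b = self.lower, self.mode, self.upper
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if b == a:
            out = np.full_like(p, c)
            return out if out.ndim else float(out)
        fc = (c - a) / (b - a)
        out = np.where(
            p <= fc,
            a + np.sqrt(np.clip(p, 0, 1) * (b - a) * (c - a)),
            b - np.sqrt(np.clip(1.0 - p, 0, 1) * (b - a) * (b - c)),
        )
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` variates by inverse-CDF sampling."""
        if n < 1:
            raise ValueError("n must be >= 1")
        u = rng.random(n)
        return np.asarray(self.quantile(u), dtype=float).reshape(n)


def triangular_quantile(dist: TriangularEF, p) -> float:
    """Inverse CDF of a triangular EF distribution (module-level wrapper)."""
    return dist.quantile(p)
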