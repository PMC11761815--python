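"""Hedges' g machinery.

Two groups of sizes ``n1`` and ``n2`` give degrees of freedom
``m = n1 + n2 - 2`` and effective size ``ntilde = n1*n2/(n1+n2)``. The
standardized mean difference ``(mean1 - mean2)/S_pooled`` is biased in small
samples; multiplying by Hedges' correction

    c(m) = Gamma(m/2) / (sqrt(m/2) * Gamma((m-1)/2))

removes the bias exactly, and ``g = c(m) * d`` then satisfies
``E(g | delta) = delta``. Conditionally on the true effect delta, g is a
scaled noncentral t: ``g = (c(m)/sqrt(ntilde)) * T`` with ``T`` noncentral t
with m degrees of freedom and noncentrality ``delta*sqrt(ntilde)``, whence
the exact conditional variance

    Var(g | delta) = (a/ntilde) * (1 + ntilde*delta^2) - delta^2,

with ``a = c(m)^2 * m/(m-2)``.

All functions are vectorized over their numeric arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import (
    DegenerateDataError,
    InvalidDesignError,
    VarianceUndefinedError,
)

__all__ = [
    "StudyRecord",
    "RawSummaries",
    "degrees_of_freedom",
    "effective_size",
    "correction_c",
    "coefficient_a",
    "hedges_g",
    "hedges_g_from_stats",
    "conditional_variance_g",
]


def degrees_of_freedom(n1, n2):
    """Degrees of freedom of the pooled SD, ``m = n1 + n2 - 2``."""
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise InvalidDesignError("both group sizes must be at least 2")
    return n1 + n2 - 2


def effective_size(n1, n2):
    """Effective sample size ``ntilde = n1*n2/(n1+n2)`` (symmetric)."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise InvalidDesignError("group sizes must be positive")
    return n1 * n2 / (n1 + n2)


def correction_c(m):
    """Hedges' small-sample bias correction c(m).

    Evaluated through log-gamma differences so that it neither overflows
    nor loses precision for large m (the raw gamma ratio overflows near
    m = 340). Strictly increasing, 0 < c(m) < 1, c(m) -> 1 as m -> inf.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 1):
        raise InvalidDesignError("degrees of freedom must be at least 1")
    return np.exp(gammaln(m / 2.0) - gammaln((m - 1.0) / 2.0)) / np.sqrt(m / 2.0)


def coefficient_a(m):
    """Variance coefficient ``a = c(m)^2 * m / (m - 2)``; a > 1, -> 1."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 2):
        raise VarianceUndefinedError("coefficient a requires m > 2")
    return correction_c(m) ** 2 * m / (m - 2.0)


def hedges_g(mean1, mean2, sd1, sd2, n1, n2):
    """Hedges' g from two-group summary statistics.

    ``g = c(m) * (mean1 - mean2) / S_pooled`` with the pooled SD using the
    divisor m = n1 + n2 - 2. Antisymmetric under swapping the groups.
    """
    m = degrees_of_freedom(np.asarray(n1), np.asarray(n2))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    sd1 = np.asarray(sd1, dtype=float)
    sd2 = np.asarray(sd2, dtype=float)
    pooled_var = ((n1 - 1.0) * sd1**2 + (n2 - 1.0) * sd2**2) / m
    if np.any(pooled_var <= 0):
        raise DegenerateDataError("pooled standard deviation is zero")
    d = (np.asarray(mean1, dtype=float) - np.asarray(mean2, dtype=float)) / np.sqrt(
        pooled_var
    )
    return correction_c(m) * d


@dataclass(frozen=True)
class RawSummaries:
    """Two-group summary statistics of one primary study."""

    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidDesignError("both group sizes must be at least 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise DegenerateDataError("standard deviations must be nonnegative")


def hedges_g_from_stats(s: RawSummaries) -> float:
    """Hedges' g of one study given as :class:`RawSummaries`."""
    return float(hedges_g(s.mean1, s.mean2, s.sd1, s.sd2, s.n1, s.n2))


def conditional_variance_g(delta, m, ntilde):
    """Exact Var(g | delta) = (a/ntilde)*(1 + ntilde*delta^2) - delta^2.

    This is the variance of the scaled noncentral-t law of g for a fixed
    true effect, i.e. the tau2 = 0 limit of the marginal study-level
    variance with mu_delta = delta.
    """
    a = coefficient_a(m)
    delta = np.asarray(delta, dtype=float)
    ntilde = np.asarray(ntilde, dtype=float)
    return a / ntilde * (1.0 + ntilde * delta**2) - delta**2


@dataclass(frozen=True)
class StudyRecord:
    """One primary study: its g value, group sizes and derived constants.

    ``m``, ``ntilde`` and ``a`` are derived from the sizes at construction
    and cached; they are the only study-specific quantities the mixture
    formulas need besides g itself.
    """

    study_id: str
    g: float
    n1: int
    n2: int
    m: int = field(init=False)
    ntilde: float = field(init=False)
    a: float = field(init=False)

    def __post_init__(self):
        m = int(degrees_of_freedom(self.n1, self.n2))
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "ntilde", float(effective_size(self.n1, self.n2)))
        if m > 2:
            object.__setattr__(self, "a", float(coefficient_a(m)))
        else:
            object.__setattr__(self, "a", float("nan"))

    @classmethod
    def from_raw(cls, study_id: str, s: RawSummaries) -> "StudyRecord":
        return cls(study_id=study_id, g=hedges_g_from_stats(s), n1=s.n1, n2=s.n2)
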