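"""Method-of-moments estimation under the mixture formulation.

The procedure has three steps:

1. an unbiased estimate of the heterogeneity tau2, built from two pooled
   plug-ins — ``C3``, an unbiased estimator of ``tau2 + mu_delta^2``, and
   ``C5``, an unbiased estimator of ``mu_delta^2`` — as
   ``tau2_raw = C3 - C5`` (truncated at zero only for reporting);
2. study-level variances from the closed-form marginal variance with C3 and
   C5 substituted for the unknown parameter combinations:
   ``sigma2_i = (a_i/ntilde_i) * (1 + ntilde_i*C3) - C5``, where by default
   a negative heterogeneity estimate inside C3 is truncated to zero first
   (see :func:`study_variance_mm`). These depend on
   a study only through its sample sizes and the pooled sums, so they are
   (essentially) uncorrelated with the study's own g — the property that
   removes the downward bias of classical inverse-variance weighting;
3. the pooled effect ``mu_hat = sum(w_i g_i)/sum(w_i)`` with
   ``w_i = 1/sigma2_i``, standard error ``1/sqrt(sum w_i)`` and a Student-t
   confidence interval on k - 1 degrees of freedom.

:class:`MixtureModelMeta` packages the three steps as a scikit-learn style
estimator; the module-level functions are thin wrappers over the same
private kernels, which are vectorized over a leading batch axis so the
bootstrap and Monte Carlo harness can run thousands of fits at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .effect_size import StudyRecord, coefficient_a, degrees_of_freedom, effective_size
from .exceptions import (
    DegenerateDataError,
    InsufficientStudiesError,
    InvalidDesignError,
    VarianceUndefinedError,
)

__all__ = [
    "MetaSample",
    "FitResult",
    "MixtureModelMeta",
    "estimate_second_raw",
    "estimate_mu_squared",
    "estimate_tau2_mm",
    "study_variance_mm",
    "estimate_mu_mm",
]


@dataclass(frozen=True)
class MetaSample:
    """An ordered collection of primary studies (g, n1, n2 per study)."""

    g: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    study_ids: tuple = None

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.g, dtype=float))
        n1 = np.atleast_1d(np.asarray(self.n1))
        n2 = np.atleast_1d(np.asarray(self.n2))
        if not (g.shape == n1.shape == n2.shape) or g.ndim != 1:
            raise InvalidDesignError("g, n1, n2 must be equal-length 1-D sequences")
        if not np.all(np.isfinite(g)):
            raise InvalidDesignError("g values must be finite")
        m = degrees_of_freedom(n1, n2)  # validates n >= 2
        if np.any(m <= 2):
            raise VarianceUndefinedError(
                "every study needs n1 + n2 - 2 > 2 for the variance formulas"
            )
        ids = self.study_ids
        if ids is None:
            ids = tuple(f"study_{i + 1}" for i in range(g.size))
        else:
            ids = tuple(str(s) for s in ids)
            if len(ids) != g.size:
                raise InvalidDesignError("study_ids length mismatch")
            if len(set(ids)) != len(ids):
                raise InvalidDesignError("study ids must be unique")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n2", n2)
        object.__setattr__(self, "study_ids", ids)

    @property
    def k(self) -> int:
        return self.g.size

    def __len__(self) -> int:
        return self.k

    @property
    def m(self) -> np.ndarray:
        return degrees_of_freedom(self.n1, self.n2)

    @property
    def ntilde(self) -> np.ndarray:
        return effective_size(self.n1, self.n2)

    @property
    def a(self) -> np.ndarray:
        return coefficient_a(self.m)

    @property
    def records(self):
        return [
            StudyRecord(study_id=s, g=float(g), n1=int(a_), n2=int(b))
            for s, g, a_, b in zip(self.study_ids, self.g, self.n1, self.n2)
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetaSample":
        ids = df["study_id"].tolist() if "study_id" in df.columns else None
        return cls(
            g=df["g"].to_numpy(dtype=float),
            n1=df["n1"].to_numpy(dtype=int),
            n2=df["n2"].to_numpy(dtype=int),
            study_ids=ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"study_id": self.study_ids, "g": self.g, "n1": self.n1, "n2": self.n2}
        )

    def resample(self, indices) -> "MetaSample":
        """Bootstrap resample; ids are re-labelled to stay unique."""
        idx = np.asarray(indices)
        return MetaSample(self.g[idx], self.n1[idx], self.n2[idx], study_ids=None)


@dataclass(frozen=True)
class FitResult:
    """Point estimates and inference for one meta-analytic method."""

    method: str
    mu_hat: float
    tau2_raw: float
    tau2_hat: float
    study_variances: np.ndarray
    weights: np.ndarray
    se_mu: float
    ci_mu: tuple
    ci_level: float
    k: int
    gweight_corr: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mu_hat": self.mu_hat,
            "tau2_raw": self.tau2_raw,
            "tau2_hat": self.tau2_hat,
            "se_mu": self.se_mu,
            "ci_level": self.ci_level,
            "ci_mu": list(self.ci_mu),
            "k": self.k,
            "gweight_corr": self.gweight_corr,
            "converged": self.converged,
            "study_variances": self.study_variances.tolist(),
            "weights": self.weights.tolist(),
        }


# ---------------------------------------------------------------------------
# batched kernels: g, a, ntilde carry an optional leading batch axis
# ---------------------------------------------------------------------------


def _c3(g, a, ntilde):
    """Unbiased plug-in for tau2 + mu_delta^2."""
    num = np.sum(g**2, axis=-1) - np.sum(a / ntilde, axis=-1)
    return num / np.sum(a, axis=-1)


def _c5(g, a, ntilde):
    """Unbiased plug-in for mu_delta^2; needs k >= 2 for the k-1 divisor."""
    k = g.shape[-1]
    abar = np.sum(a, axis=-1) / k
    gbar = np.mean(g, axis=-1)
    first = (k * gbar**2 - np.sum(a / (k * ntilde), axis=-1)) / abar
    return abar / (k - 1) * (first - _c3(g, a, ntilde))


def _study_var(a, ntilde, c3, c5):
    return a / ntilde * (1.0 + ntilde * c3[..., None]) - c5[..., None]


def _pearson(x, w):
    """Row-wise Pearson correlation; NaN where either vector is constant."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    xc = x - x.mean(axis=-1, keepdims=True)
    wc = w - w.mean(axis=-1, keepdims=True)
    sx = np.sqrt(np.sum(xc**2, axis=-1))
    sw = np.sqrt(np.sum(wc**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(xc * wc, axis=-1) / (sx * sw)
    return np.where((sx > 0) & (sw > 0), r, np.nan)


def _plugin_c3(c3, c5, plugin):
    """Second-moment plug-in entering the study variances.

    ``"truncated"`` replaces a negative heterogeneity estimate by zero
    inside the plug-in (C3_eff = max(C3 - C5, 0) + C5), as in the reported
    simulation results; ``"raw"`` uses C3 as is.
    """
    if plugin == "truncated":
        return np.maximum(c3 - c5, 0.0) + c5
    if plugin == "raw":
        return c3
    raise ValueError(f"unknown plugin {plugin!r}; use 'truncated' or 'raw'")


def _mm_batch(g, a, ntilde, var_floor=1e-8, plugin="truncated"):
    """Vectorized mixture-model fit over a leading batch axis.

    Returns (mu_hat, tau2_raw, study_var_floored, weights, se_mu).
    """
    c3 = _c3(g, a, ntilde)
    c5 = _c5(g, a, ntilde)
    sv = np.maximum(_study_var(a, ntilde, _plugin_c3(c3, c5, plugin), c5), var_floor)
    w = 1.0 / sv
    sw = np.sum(w, axis=-1)
    mu = np.sum(w * g, axis=-1) / sw
    return mu, c3 - c5, sv, w, 1.0 / np.sqrt(sw)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def estimate_second_raw(sample: MetaSample) -> float:
    """Unbiased estimate of tau2 + mu_delta^2 (no truncation)."""
    if sample.k < 1:
        raise InsufficientStudiesError("need at least one study")
    return float(_c3(sample.g, sample.a, sample.ntilde))


def estimate_mu_squared(sample: MetaSample) -> float:
    """Unbiased estimate of mu_delta^2; requires k >= 2."""
    if sample.k < 2:
        raise InsufficientStudiesError("need at least two studies")
    return float(_c5(sample.g, sample.a, sample.ntilde))


def estimate_tau2_mm(sample: MetaSample):
    """Unbiased heterogeneity estimate: (tau2_raw, tau2_truncated)."""
    if sample.k < 2:
        raise InsufficientStudiesError("need at least two studies")
    raw = estimate_second_raw(sample) - estimate_mu_squared(sample)
    return raw, max(0.0, raw)


def study_variance_mm(
    sample: MetaSample, var_floor: float = 1e-8, plugin: str = "truncated"
) -> np.ndarray:
    """Estimated study-level variances of g under the mixture model.

    Each variance depends on its study only through (a_i, ntilde_i) plus the
    pooled C3/C5 sums, never through the study's own g beyond its equal
    share in those sums. By default a negative heterogeneity estimate is
    truncated to zero inside the plug-in (``plugin="truncated"``); pass
    ``plugin="raw"`` for the untruncated sums. Nonpositive values (possible
    in pathological small samples) are floored at ``var_floor`` with a
    warning; an all-nonpositive sample raises :class:`DegenerateDataError`.
    """
    if sample.k < 2:
        raise InsufficientStudiesError("need at least two studies")
    c3 = np.asarray(_c3(sample.g, sample.a, sample.ntilde))
    c5 = np.asarray(_c5(sample.g, sample.a, sample.ntilde))
    sv = _study_var(sample.a, sample.ntilde, _plugin_c3(c3, c5, plugin), c5)
    if np.all(sv <= 0):
        raise DegenerateDataError("all estimated study variances are nonpositive")
    if np.any(sv <= 0):
        warnings.warn(
            "nonpositive estimated study variance floored at "
            f"{var_floor:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        sv = np.maximum(sv, var_floor)
    return sv


def estimate_mu_mm(
    sample: MetaSample,
    ci_level: float = 0.95,
    var_floor: float = 1e-8,
    plugin: str = "truncated",
) -> FitResult:
    """Full three-step mixture-model fit returning a :class:`FitResult`."""
    est = MixtureModelMeta(ci_level=ci_level, var_floor=var_floor, plugin=plugin)
    est.fit(sample)
    return est.result_


def _t_ci(mu, se, k, level):
    half = stats.t.ppf(0.5 + level / 2.0, df=k - 1) * se
    return (mu - half, mu + half)


def _coerce_sample(X) -> MetaSample:
    if isinstance(X, MetaSample):
        return X
    if isinstance(X, pd.DataFrame):
        return MetaSample.from_dataframe(X)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InvalidDesignError(
            "array input must have shape (k, 3): columns g, n1, n2"
        )
    return MetaSample(X[:, 0], X[:, 1].astype(int), X[:, 2].astype(int))


class MixtureModelMeta(BaseEstimator):
    """Mixture-model random-effects meta-analysis of Hedges' g.

    Parameters
    ----------
    ci_level : float, default 0.95
        Two-sided confidence level of the Student-t interval for mu_delta
        (k - 1 degrees of freedom).
    var_floor : float, default 1e-8
        Lower bound applied to estimated study variances so the weights
        stay finite.
    plugin : {"truncated", "raw"}, default "truncated"
        Whether a negative heterogeneity estimate is truncated to zero
        inside the study-variance plug-in. Truncation reproduces the
        reported confidence-interval coverage at small tau2; the raw
        variant keeps the fully unbiased plug-in sums.

    Attributes
    ----------
    mu_ : float
        Inverse-variance weighted estimate of the mean true effect.
    tau2_raw_, tau2_ : float
        Untruncated and truncated (at zero) heterogeneity estimates. The
        study variances and weights always use the raw plug-ins.
    study_variances_, weights_ : ndarray of shape (k,)
    se_mu_ : float
        Standard error of ``mu_``, ``1/sqrt(sum of weights)``.
    ci_mu_ : tuple of float
    gweight_corr_ : float
        Pearson correlation between the g values and the weights (NaN when
        either is constant, e.g. equal sample sizes).

    Examples
    --------
    >>> import pandas as pd
    >>> from mixturemeta import MixtureModelMeta
    >>> df = pd.DataFrame({"g": [0.2, 0.5, 0.8], "n1": [10, 15, 20],
    ...                    "n2": [10, 15, 20]})
    >>> round(MixtureModelMeta().fit(df).mu_, 4)
    0.5685
    """

    method = "MM"

    def __init__(
        self,
        ci_level: float = 0.95,
        var_floor: float = 1e-8,
        plugin: str = "truncated",
    ):
        self.ci_level = ci_level
        self.var_floor = var_floor
        self.plugin = plugin

    def fit(self, X, y=None):
        """Fit the three-step procedure on a study table.

        ``X`` may be a :class:`MetaSample`, a DataFrame with columns
        ``g, n1, n2`` (optional ``study_id``), or an array of shape (k, 3).
        """
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        sample = _coerce_sample(X)
        if sample.k < 2:
            raise InsufficientStudiesError("need at least two studies")
        tau2_raw, tau2_hat = estimate_tau2_mm(sample)
        sv = study_variance_mm(sample, var_floor=self.var_floor, plugin=self.plugin)
        w = 1.0 / sv
        self.sample_ = sample
        self.k_ = sample.k
        self.tau2_raw_ = float(tau2_raw)
        self.tau2_ = float(tau2_hat)
        self.study_variances_ = sv
        self.weights_ = w
        self.mu_ = float(np.sum(w * sample.g) / np.sum(w))
        self.se_mu_ = float(1.0 / np.sqrt(np.sum(w)))
        self.ci_mu_ = _t_ci(self.mu_, self.se_mu_, sample.k, self.ci_level)
        self.gweight_corr_ = float(_pearson(sample.g, w))
        return self

    @property
    def result_(self) -> FitResult:
        return FitResult(
            method=self.method,
            mu_hat=self.mu_,
            tau2_raw=self.tau2_raw_,
            tau2_hat=self.tau2_,
            study_variances=self.study_variances_,
            weights=self.weights_,
            se_mu=self.se_mu_,
            ci_mu=self.ci_mu_,
            ci_level=self.ci_level,
            k=self.k_,
            gweight_corr=self.gweight_corr_,
        )
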