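"""Classical random-effects baselines: DerSimonian-Laird and REML.

Both methods build each study's variance the classical way — an estimate of
the conditional sampling variance of g with the study's *own* g plugged in
for the unknown true effect, plus the heterogeneity estimate. Because that
conditional variance increases with |g|, the resulting weights correlate
negatively with the g values, which is precisely the covariation the
mixture-model procedure avoids; :func:`weight_correlation` measures it.

DerSimonian-Laird estimates tau2 in closed form from Cochran's Q with
fixed-effect weights; REML solves the restricted-likelihood estimating
equation of the normal-normal model by a damped fixed-point iteration. The
kernels accept a leading batch axis so simulations and bootstraps can fit
many samples at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .effect_size import coefficient_a
from .estimators import (
    FitResult,
    MetaSample,
    _coerce_sample,
    _pearson,
    _t_ci,
)
from .exceptions import (
    ConvergenceError,
    InsufficientStudiesError,
    VarianceUndefinedError,
)

__all__ = [
    "conditional_variance_estimate",
    "DerSimonianLaird",
    "RestrictedML",
    "estimate_dl",
    "estimate_reml",
    "weight_correlation",
]


def conditional_variance_estimate(g, m, ntilde, form: str = "exact"):
    """Estimated conditional (sampling) variance of g.

    ``form="exact"`` plugs g into the exact formula,
    ``(a/ntilde)*(1 + ntilde*g^2) - g^2``; ``form="large-sample"`` is the
    common approximation ``1/ntilde + g^2/(2*(n1+n2))`` written via
    ``m + 2 = n1 + n2``. Both increase with \\|g\\| for fixed sizes — the
    covariation the mixture model removes.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    ntilde = np.asarray(ntilde, dtype=float)
    if form == "exact":
        a = coefficient_a(m)
        return a / ntilde * (1.0 + ntilde * g**2) - g**2
    if form == "large-sample":
        if np.any(m <= 2):
            raise VarianceUndefinedError("m must exceed 2")
        return 1.0 / ntilde + g**2 / (2.0 * (m + 2.0))
    raise ValueError(f"unknown conditional variance form: {form!r}")


# ---------------------------------------------------------------------------
# batched kernels
# ---------------------------------------------------------------------------


def _dl_batch(g, v):
    """DerSimonian-Laird tau2 and pooled mean over a leading batch axis.

    Returns (mu, tau2, se_mu) using fixed-effect weights for Q and
    random-effects weights 1/(v + tau2) for mu.
    """
    k = g.shape[-1]
    w = 1.0 / v
    sw = np.sum(w, axis=-1)
    mu_fe = np.sum(w * g, axis=-1) / sw
    q = np.sum(w * (g - mu_fe[..., None]) ** 2, axis=-1)
    denom = sw - np.sum(w**2, axis=-1) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
    ws = 1.0 / (v + tau2[..., None])
    sws = np.sum(ws, axis=-1)
    mu = np.sum(ws * g, axis=-1) / sws
    return mu, tau2, 1.0 / np.sqrt(sws)


def _reml_batch(g, v, tol=1e-8, max_iter=500):
    """REML fixed-point iteration for tau2 over a leading batch axis.

    Solves tau2 = sum(w^2 ((g-mu)^2 - v))/sum(w^2) + 1/sum(w) with
    w = 1/(v + tau2), floored at zero each step.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    _, tau2, _ = _dl_batch(g, v)  # DL as starting value
    converged = np.zeros(np.shape(tau2), dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / (v + tau2[..., None])
        sw = np.sum(w, axis=-1)
        mu = np.sum(w * g, axis=-1) / sw
        num = np.sum(w**2 * ((g - mu[..., None]) ** 2 - v), axis=-1)
        new = np.maximum(0.0, num / np.sum(w**2, axis=-1) + 1.0 / sw)
        converged = np.abs(new - tau2) < tol
        tau2 = new
        if np.all(converged):
            break
    w = 1.0 / (v + tau2[..., None])
    sw = np.sum(w, axis=-1)
    mu = np.sum(w * g, axis=-1) / sw
    return mu, tau2, 1.0 / np.sqrt(sw), converged, it


def weight_correlation(sample: MetaSample, weights) -> float:
    """Pearson correlation between the g values and the weights.

    NaN (reported as missing, not an error) when either vector is
    constant; requires at least three studies.
    """
    if sample.k < 3:
        raise InsufficientStudiesError("correlation needs at least three studies")
    return float(_pearson(sample.g, np.asarray(weights, dtype=float)))


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class _ClassicalREM(BaseEstimator):
    """Shared fit plumbing of the DL and REML baselines."""

    method = ""

    def __init__(
        self,
        ci_level: float = 0.95,
        conditional_variance_form: str = "exact",
        ci_dist: str = "z",
    ):
        self.ci_level = ci_level
        self.conditional_variance_form = conditional_variance_form
        self.ci_dist = ci_dist

    def _tau2_mu(self, g, v):
        raise NotImplementedError

    def fit(self, X, y=None):
        sample = _coerce_sample(X)
        if sample.k < 2:
            raise InsufficientStudiesError("need at least two studies")
        v = conditional_variance_estimate(
            sample.g, sample.m, sample.ntilde, form=self.conditional_variance_form
        )
        mu, tau2, se = self._tau2_mu(sample.g, v)
        self.sample_ = sample
        self.k_ = sample.k
        self.sampling_variances_ = v
        self.tau2_raw_ = float(tau2)  # already truncated by construction
        self.tau2_ = float(tau2)
        self.study_variances_ = v + tau2
        self.weights_ = 1.0 / self.study_variances_
        self.mu_ = float(mu)
        self.se_mu_ = float(se)
        if self.ci_dist == "t":
            self.ci_mu_ = _t_ci(self.mu_, self.se_mu_, sample.k, self.ci_level)
        else:
            half = stats.norm.ppf(0.5 + self.ci_level / 2.0) * self.se_mu_
            self.ci_mu_ = (self.mu_ - half, self.mu_ + half)
        self.gweight_corr_ = float(_pearson(sample.g, self.weights_))
        return self

    @property
    def result_(self) -> FitResult:
        return FitResult(
            method=self.method,
            mu_hat=self.mu_,
            tau2_raw=self.tau2_raw_,
            tau2_hat=self.tau2_,
            study_variances=np.asarray(self.study_variances_),
            weights=np.asarray(self.weights_),
            se_mu=self.se_mu_,
            ci_mu=self.ci_mu_,
            ci_level=self.ci_level,
            k=self.k_,
            gweight_corr=self.gweight_corr_,
            converged=getattr(self, "converged_", True),
            n_iter=getattr(self, "n_iter_", 0),
        )


class DerSimonianLaird(_ClassicalREM):
    """DerSimonian-Laird moment estimator of (mu_delta, tau2).

    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with
    fixed-effect weights w = 1/v; the pooled mean then uses weights
    1/(v + tau2).
    """

    method = "DL"

    def _tau2_mu(self, g, v):
        return _dl_batch(g, v)


class RestrictedML(_ClassicalREM):
    """Restricted maximum-likelihood estimator of the normal-normal model.

    Fixed-point iteration on the REML estimating equation, tau2
    floored at zero each step; raises :class:`ConvergenceError` if the
    iteration cap is reached without convergence.
    """

    method = "REML"

    def __init__(
        self,
        ci_level: float = 0.95,
        conditional_variance_form: str = "exact",
        ci_dist: str = "z",
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        super().__init__(
            ci_level=ci_level,
            conditional_variance_form=conditional_variance_form,
            ci_dist=ci_dist,
        )
        self.tol = tol
        self.max_iter = max_iter

    def _tau2_mu(self, g, v):
        mu, tau2, se, converged, n_iter = _reml_batch(
            g, v, tol=self.tol, max_iter=self.max_iter
        )
        self.converged_ = bool(np.all(converged))
        self.n_iter_ = int(n_iter)
        if not self.converged_:
            raise ConvergenceError(
                f"REML did not converge in {self.max_iter} iterations "
                f"(last tau2 = {float(tau2):.6g})"
            )
        return mu, tau2, se


def estimate_dl(sample, ci_level: float = 0.95, **kwargs) -> FitResult:
    """DerSimonian-Laird fit returning a :class:`FitResult`."""
    return DerSimonianLaird(ci_level=ci_level, **kwargs).fit(sample).result_


def estimate_reml(sample, ci_level: float = 0.95, **kwargs) -> FitResult:
    """REML fit returning a :class:`FitResult`."""
    return RestrictedML(ci_level=ci_level, **kwargs).fit(sample).result_
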