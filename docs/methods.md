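# Methods

## Model

A meta-analysis pools standardized mean differences from k independent
two-group studies. Study i reports Hedges' g_i computed from groups of
sizes N1_i and N2_i; write m_i = N1_i + N2_i − 2 for the degrees of
freedom of the pooled SD, ñ_i = N1_i·N2_i/(N1_i + N2_i) for the effective
size, c(m) = Γ(m/2)/(√(m/2)·Γ((m−1)/2)) for the small-sample bias
correction, and a_i = c(m_i)²·m_i/(m_i − 2). Under a random-effects view
the true effect δ_i of each study is itself a draw from a latent
distribution with mean μ_Δ and variance τ² (the heterogeneity).

Conditionally on δ, g is a scaled noncentral t,

    g | δ  =  (c(m)/√ñ) · T,   T ~ t(m, ncp = δ√ñ),

so its marginal (study-level) law is the continuous mixture of that
conditional law over the latent distribution of δ. This package works
with the exact moments of that mixture rather than with the classical
"τ² + conditional sampling variance" decomposition, because the
conditional variance of g depends on δ itself — plugging each study's own
g into it (the classical practice) manufactures a correlation between
effect sizes and weights and a downward bias in the pooled estimate.

Closed forms used throughout (valid for *any* latent family with finite
moments of the required order; normality of δ is never needed):

- mean: E(g) = μ_Δ, for any m, ñ;
- variance: σ²_G = (a/ñ)·(1 + ñ·(τ² + μ_Δ²)) − μ_Δ² (requires m > 2);
- third central moment:
  μ₃ = (c³/ñ)·m^{3/2}·Γ((m−3)/2)/(2√2·Γ(m/2))·(3μ_Δ + E(δ³)·ñ)
  − 3μ_Δσ²_G − μ_Δ³ (requires m > 3), and skewness γ = μ₃/σ³_G.

A general central moment of order r is implemented in
`moments.central_moment` as a double sum over binomial terms involving
c(m), ñ, the raw latent moments E(δ^s), and gamma-function ratios. One
typographical point deserves a note: the printed form of this general
expression carries a factor (m/2)^{r/2}, which does not reduce to the
closed-form variance at r = 2. The implementation uses (m/2)^{(r−k)/2}
(k the outer summation index), which reduces *exactly* to the variance at
r = 2 and to the third-moment expression at r = 3 (verified symbolically
by hand-reduction and numerically against quadrature of the marginal
density at 10⁻⁶ relative over a parameter grid). The discrepancy is
documented rather than hidden; the tests pin both reductions.

At the meta-analysis level the k studies form a finite equal-weight
mixture of study-level laws that differ only through (m_i, ñ_i). Because
every component shares the mean μ_Δ, the law of total variance and the
law of total cumulance give the meta-level variance and third moment as
the plain averages of the per-study ones.

## Estimation

Three steps (`estimators.MixtureModelMeta`):

1. **Heterogeneity.** Two pooled, unbiased plug-ins:
   C3 = [Σg_i² − Σ(a_i/ñ_i)]/Σa_i estimates τ² + μ_Δ², and
   C5 = (Σa_i/k)/(k−1) · [(k·ḡ² − Σa_i/(k·ñ_i))/(Σa_i/k) − C3]
   estimates μ_Δ². The heterogeneity estimate is τ̂²_raw = C3 − C5,
   unbiased by construction; the reported τ̂² truncates it at zero.
2. **Study variances.** σ̂²_i = (a_i/ñ_i)·(1 + ñ_i·C3_eff) − C5 with
   C3_eff = max(τ̂²_raw, 0) + C5 by default (`plugin="truncated"`).
   These depend on study i only through its sample sizes and the pooled
   sums, which is what removes the g–weight covariation.
3. **Pooled effect.** μ̂_Δ = Σw_i g_i/Σw_i with w_i = 1/σ̂²_i,
   SE = 1/√Σw_i, and a Student-t interval on k − 1 degrees of freedom
   (level configurable, default 95%).

**Truncated vs raw plug-in.** Whether the truncated or the raw
heterogeneity estimate should enter step 2 is a genuinely open design
point: the raw plug-in preserves the unbiasedness algebra exactly, while
truncation matches how negative estimates are handled in reported
analyses. We measured both at 100,000 replicates per condition: μ̂_Δ is
unaffected (|bias| < 0.0005 either way), but the t-interval coverage at
small heterogeneity (τ² = 0.1, k = 15) is 0.918 with the raw plug-in and
0.952 with truncation — only the truncated variant reproduces the
reference coverage behaviour (94–95% at small τ²). Truncation is
therefore the default and `plugin="raw"` remains available.

Degenerate cases: a study variance that comes out nonpositive (possible
in pathological small samples) is floored at `var_floor` (default 1e−8)
with a warning; a sample where *all* variances are nonpositive is an
error. k = 2 is the minimum (the k − 1 divisor in C5); every study needs
m > 2.

## Baselines

`comparators.DerSimonianLaird` and `comparators.RestrictedML` implement
the classical pipeline: each study's sampling variance is the exact
conditional variance with the study's own g plugged in,
v_i = (a_i/ñ_i)(1 + ñ_i g_i²) − g_i² (a large-sample approximation is
available behind `conditional_variance_form="large-sample"`). DL solves
the Q-statistic moment equation in closed form with truncation at zero;
REML iterates the restricted-likelihood fixed point
τ² ← Σw_i²[(g_i−μ̂)² − v_i]/Σw_i² + 1/Σw_i, w_i = 1/(v_i+τ²), floored at
zero, tolerance 1e−8, at most 500 iterations, started from the DL value.
The REML solution is cross-checked in the tests against a brute-force
profile-likelihood grid search (step 1e−4). Their CIs use the normal
quantile, as their reference implementations do. Exact numerical
agreement with any particular R implementation's internals is not a goal.

## Synthetic data

The generator (`simulation`) mirrors a psychology-style meta-analytic
setting: δ_i ~ N(μ_Δ, τ²) with μ_Δ = 0.5 by default; size pairs drawn
equiprobably from eight small-to-moderate designs
(5,5),(10,10),(5,15),(15,15),(10,20),(20,20),(10,30),(15,25); τ² varied
over 0.1–0.9 and k over 15/30/45 in the evaluation grid. Two sampling
modes produce identically distributed g (a two-sample KS check at 1e5
draws is in the suite): drawing individual N(δ,1)/N(0,1) scores, or
drawing g directly from the scaled noncentral-t via one normal and one
chi-square variate. Direct mode is the default (exact and roughly
sample-size-fold faster).

What the generator does *not* emulate — hence what passing tests do not
establish about real data: publication bias or any selection on
significance, non-normal or skewed latent effect distributions (the
moment formulas support them; the replication grid does not exercise
them), unequal true variances between arms, dependent effect sizes, and
measurement artefacts. Conclusions about estimator bias and coverage are
conditional on the normal-normal generating model above.

## Experiments and problem sizes

- **Moment accuracy**: 10⁶ simulated studies per run (the package's
  desk-scale default; the same code accepts larger counts). Agreement
  between empirical and closed-form mean/variance/skewness is asserted
  within 3 Monte Carlo SEs, with SEs taken from the spread of 100
  batch-wise statistics.
- **Estimator grid**: 15 conditions (τ² ∈ {0.1,…,0.9} × k ∈ {15,30,45})
  at 2,000 replicates each, vectorised over replicates. Bias, variance,
  RMSE (the decomposition RMSE² = bias² + variance is asserted),
  coverage, and mean g–weight Pearson correlation per method. The MM
  correlation's true magnitude is in the third decimal, so the dedicated
  check raises replication to 500,000 (closed-form, seconds) to separate
  it from Monte Carlo noise.
- **Bootstrap**: percentile intervals for τ² from B = 1,000 resamples of
  the study set with replacement (estimator re-run per resample,
  vectorised); coverage ordering across methods is checked directionally
  at 300 replicates × 400 resamples.

Every simulation output is a pure function of (condition, seed): one
numpy `Generator` seeded per run drives all draws in a fixed order. The
per-replicate work is batched rather than streamed, which is why the
harness is fast; determinism is asserted in the tests.

## Numerical choices

- c(m) through log-gamma differences (raw gamma ratios overflow near
  m ≈ 340); monotone to ~1e−8 at m ~ 1e6 where log-gamma's few-ulp error
  dominates the tiny increments.
- Gamma-argument preconditions enforced as errors (m > 2 for variances,
  m > 3 for third moments, m > r in the general formula) instead of
  returning infinities.
- Marginal density via 96-node Gauss–Hermite quadrature for the normal
  latent family; adaptive quadrature over μ_Δ ± 10τ for any other family
  exposing a density. τ² = 0 degenerates to the conditional density.
- CSV floats are parsed through Python's correctly-rounded `float` (the
  fast pandas parser is not shortest-round-trip) so tables round-trip
  bit-exactly.

## Known limitations

- No analytic variance or distribution for τ̂²_MM: its CI comes from the
  (conservative) percentile bootstrap.
- The worked-example tables bundled under `tests/data` are synthetic
  stand-ins generated by this package's simulator (the original
  supplementary datasets are not redistributable here); the pipeline is
  exercised end-to-end, but the published example estimates are not
  reproduced from the original data.
- Knapp–Hartung adjustments, prediction intervals, moderators, and other
  τ² estimators (Paule–Mandel, Sidik–Jonkman, …) are out of scope.
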