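# mixturemeta

Random-effects meta-analysis of standardized mean differences (Hedges' g),
formulated as a mixture model.

## The problem

A meta-analyst pools effect sizes g_1, …, g_k from k two-group studies,
assuming each study's true effect δ_i is drawn from a latent distribution
with mean μ_Δ and heterogeneity variance τ². The classical random-effects
machinery builds each study's variance as τ̂² plus an estimate of the
*conditional* sampling variance of g — a quantity that depends on the
study's own g. That plug-in makes the inverse-variance weights correlate
negatively with the effect sizes, which biases the pooled estimate
downward, and it is conceptually the wrong variance: the study-level
variance of g is the variance of its *marginal* law,

    h_G(g) = ∫ f_G(g | δ) f_Δ(δ) dδ,

the mixture of the scaled noncentral-t conditional law of g over the
latent distribution of δ. This package implements that mixture view:

- exact closed-form mean, variance and skewness of g at the study level
  (σ²_G = (a/ñ)(1 + ñ(τ² + μ_Δ²)) − μ_Δ², with a = c(m)²m/(m−2) and
  ñ = N1N2/(N1+N2)) and at the meta-analysis level (equal-weight finite
  mixture over the studies' size pairs), plus a general central moment of
  any order for any latent family via its raw moments;
- unbiased method-of-moments estimators: τ̂²_MM from two pooled plug-ins,
  study variances that depend on a study only through its sample sizes,
  and an inverse-variance weighted μ̂_Δ whose weights are (essentially)
  uncorrelated with the g values, with a Student-t CI;
- classical baselines (DerSimonian–Laird, REML) for comparison, a
  percentile bootstrap for τ², and a Monte Carlo harness that reproduces
  the evaluation experiments.

It is aimed at methodologists studying heterogeneity estimators and at
meta-analysts who want an SMD pipeline free of the g–weight covariation.

## Worked example

```python
import pandas as pd
from mixturemeta import MixtureModelMeta
from mixturemeta.comparators import DerSimonianLaird

studies = pd.DataFrame({
    "g":  [0.2, 0.5, 0.8],
    "n1": [10, 15, 20],
    "n2": [10, 15, 20],
})
mm = MixtureModelMeta().fit(studies)
print(f"mu = {mm.mu_:.4f}  tau2 = {mm.tau2_:.4f} (raw {mm.tau2_raw_:.4f})")
print(f"95% CI = [{mm.ci_mu_[0]:.4f}, {mm.ci_mu_[1]:.4f}]")
print(f"DL mu = {DerSimonianLaird().fit(studies).mu_:.4f}")
```

prints

```
mu = 0.5685  tau2 = 0.0000 (raw -0.0613)
95% CI = [-0.3618, 1.4988]
DL mu = 0.5607
```

The raw heterogeneity estimate is negative (three studies, little spread
beyond sampling noise), so the reported τ̂² truncates to zero; the pooled
effect 0.5685 weights the three g values by the inverse of their
estimated marginal variances, and the wide t-interval (k − 1 = 2 degrees
of freedom) reflects how little three small studies constrain μ_Δ.

The same fits run from a shell on a CSV study table
(`study_id,g,n1,n2` or `study_id,mean1,sd1,n1,mean2,sd2,n2`):

```bash
mixturemeta fit studies.csv --method mm,dl,reml --bootstrap 1000 --seed 1
mixturemeta moments --mu 0.5 --tau2 0.1 --sizes 15,15
mixturemeta simulate config.yaml --out results/
```

`mixturemeta moments` at μ_Δ = 0.5, τ² = 0.1, N1 = N2 = 15 prints
`variance=0.24272  skewness=0.12139`: even with a symmetric (normal)
latent distribution the marginal law of g is right-skewed, which is why
symmetry-based funnel-plot diagnostics over-reject in the absence of any
publication bias.

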