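# latentq

Bayesian **quantile structural equation modelling** for questionnaire-based
mental-health epidemiology.

Occupational-health studies often summarise several correlated
psychological scores (psychological distress, anxiety, depression) into a
single latent "psychological problems profile" and ask how strongly latent
stressor domains — themselves measured by many stressful-life-event items —
are associated with it.  Profile scores are typically right-skewed, and the
association of interest may differ between mildly and severely affected
employees.  `latentq` addresses both problems at once: the structural part
of the SEM is a *quantile* regression of the latent response on the latent
predictors, so the whole conditional distribution is modelled, not just its
mean.

## Model

For participant *i* with indicator vector **y**ᵢ (14 indicators by default)
and fixed covariates **x**ᵢ:

```
measurement:  yᵢ = μ + Λ ωᵢ + εᵢ,            εᵢ ~ N(0, Ψ)   (Ψ diagonal)
structural:   ηᵢ = b'xᵢ + γ₁ ξᵢ₁ + γ₂ ξᵢ₂ + δᵢ,  δᵢ ~ ALD(τ, σ)
```

where ωᵢ = (ηᵢ, ξᵢ₁, ξᵢ₂) collects the latent response (the psychological
problems profile, measured by 3 indicators) and two latent stressor domains
("socioeconomic", 7 domain scores; "personal", 4 domain scores), Λ is
block-sparse with the first indicator of each factor anchored at loading 1,
and ξᵢ ~ N(0, Φ).  The asymmetric Laplace distribution (ALD) has its
τ-quantile at zero, so maximising its likelihood minimises the
quantile-regression check loss ρ_τ(u) = u(τ − 1[u<0]): the structural
equation models the τ-th quantile of η.  Each τ is fitted independently by
a Gibbs sampler built on the normal–exponential ALD augmentation
δ = k₁e + k₂√(σe)·z with e ~ Exp(mean σ), k₁ = (1−2τ)/(τ(1−τ)),
k₂² = 2/(τ(1−τ)).

The package also provides:

* **scoring** — GHQ-12 (bimodal 0-0-1-1, range 0–12), HADS (two 0–21
  subscales, caseness ≥ 8), an 11-domain / 46-item stressful-life-event
  questionnaire (0–5 intensity scale), effort–reward imbalance and IPAQ
  physical activity, with a >10 % missingness exclusion rule;
* **factor models** — single-factor profile extraction, stressor EFA with
  varimax rotation, quartile descriptive tables;
* **classical evaluation** — maximum-likelihood mean-regression SEM with
  CFI / TLI / RMSEA, and posterior predictive p-values for the quantile
  model;
* **synthetic data** — a generator with known ground truth for all of the
  above, used throughout the test suite;
* a CLI (`latentq score | simulate | factors | fit | eval | run |
  samplesize`).

## Worked example

Fit the model to a synthetic cohort of n = 1500 with generating structural
coefficients γ = (0.2, 0.8) and a right-skewed structural error
(moment skewness 0.9):

```python
from latentq import default_truth, generate_dataset, extract_profile, efa_stressors
from latentq.qsem import QSemSpec, McmcSettings, fit_all_quantiles
from latentq.synthetic import PSYCH_INDICATORS, SOCIOECONOMIC_DOMAINS, PERSONAL_DOMAINS

truth = default_truth(n=1500, seed=42)
indicators, covariates, _ = generate_dataset(truth)

profile = extract_profile(indicators[PSYCH_INDICATORS])
print(f"profile variance explained: {profile.variance_explained:.2f} %")
efa = efa_stressors(indicators[SOCIOECONOMIC_DOMAINS + PERSONAL_DOMAINS])
print(f"two-factor EFA variance explained: {efa.variance_explained:.2f} %")

spec = QSemSpec(
    eta_indicators=PSYCH_INDICATORS,
    xi1_indicators=SOCIOECONOMIC_DOMAINS,
    xi2_indicators=PERSONAL_DOMAINS,
    covariates=list(covariates.columns),
)
mcmc = McmcSettings(chains=2, iterations=2500, burn_in=1000, seed=11)
grid = fit_all_quantiles(indicators, covariates, spec, mcmc)
g = grid.coefficient_grid
print(g[g["parameter"].str.startswith("gamma_")][
    ["tau", "parameter", "mean", "ci_2.5", "ci_97.5", "significant"]
].round(3).to_string(index=False))
```

Output:

```
profile variance explained: 78.19 %
two-factor EFA variance explained: 45.36 %
 tau           parameter  mean  ci_2.5  ci_97.5  significant
0.05 gamma_socioeconomic 0.210   0.151    0.277         True
0.05      gamma_personal 0.811   0.757    0.866         True
0.25 gamma_socioeconomic 0.221   0.159    0.284         True
0.25      gamma_personal 0.784   0.699    0.903         True
0.50 gamma_socioeconomic 0.233   0.168    0.295         True
0.50      gamma_personal 0.782   0.681    0.887         True
0.75 gamma_socioeconomic 0.180   0.125    0.244         True
0.75      gamma_personal 0.918   0.817    1.028         True
0.95 gamma_socioeconomic 0.170   0.075    0.254         True
0.95      gamma_personal 0.989   0.921    1.128         True
```

The single profile factor explains ≈ 78 % of the variance of the three
psychological indicators, the two-factor stressor solution ≈ 45 % of the
variance of the 11 domains, and the fitted quantile paths recover the
generating structure: the personal-stressor coefficient dominates the
socioeconomic one at every quantile and grows toward the upper quantiles
(the generating error is right-skewed), while the socioeconomic coefficient
stays roughly flat around its generating value 0.2.  A coefficient is
flagged significant when its equal-tailed 95 % credible interval excludes
zero.

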