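# Methods

## The model

`latentq` estimates a structural equation model whose measurement part is
a conventional linear factor model and whose structural part is a quantile
regression among latent variables:

```
yᵢ = μ + Λ ωᵢ + εᵢ,   εᵢ ~ N(0, Ψ),  Ψ diagonal
ηᵢ = b'xᵢ + γ'ξᵢ + δᵢ,   δᵢ ~ ALD(τ, σ)
ξᵢ ~ N(0, Φ)
```

with ωᵢ = (ηᵢ, ξᵢ₁, ξᵢ₂).  The default indicator map is 3 psychological
scores on the latent response η and 7 + 4 stressor-domain scores on the
two latent predictors.  Covariates **x** enter the structural equation as
fixed (error-free) regressors.  The asymmetric Laplace working likelihood
fixes the τ-quantile of δ at zero, so the fitted structural surface is the
τ-th conditional quantile of the latent response.  Indicators are treated
as continuous; ordinal (probit-link) measurement is out of scope.

Assumptions worth keeping in mind: conditional normality of measurement
errors, linearity of both parts, latent predictors independent of the
covariates, and an exact ALD structural error *as a working likelihood* —
the quantile interpretation is what matters, not literal ALD data.

### Identification

Each factor is identified by fixing the loading of its first ("anchor")
indicator at 1, keeping structural coefficients on the indicator scale;
factor variances are free.  The location of η is not absorbed into the
free measurement intercepts because the ALD pins the τ-quantile of δ at
zero; translating η would translate δ and change the likelihood.  The
profile factor's sign is fixed by the positive anchor loading (higher
score = worse mental health).

### Priors (defaults, configurable)

* free loadings and intercepts: N(0, 10²)
* structural coefficients γ, b: N(0, 10²)
* uniquenesses Ψⱼⱼ and ALD scale σ: Inverse-Gamma(0.01, 0.01)
* latent-predictor covariance Φ: Inverse-Wishart(I₂, 4)

These are weakly informative on the standardized indicator scale (below).

### Gibbs sampler

The ALD is augmented as δ = k₁e + k₂√(σe)·z, e ~ Exponential(mean σ),
k₁ = (1−2τ)/(τ(1−τ)), k₂² = 2/(τ(1−τ)).  One sweep updates:

1. **e**ᵢ | rest ~ GIG(½, δᵢ²/(k₂²σ), 1/(2τ(1−τ)σ)).  For index ½ the GIG
   is the reciprocal of an inverse Gaussian, so eᵢ is sampled exactly via
   the Michael–Schucany–Haas transform — no rejection loop.  δᵢ² is
   floored at 1e−12 and eᵢ at 1e−12 to avoid degenerate conditionals.
2. **ω**ᵢ | rest — trivariate normal.  The structural prior precision is a
   rank-one update of a shared matrix, so the n 3×3 systems are built and
   factorised in one batched operation.
3. (μⱼ, λⱼ) | rest — conjugate normal row updates, anchors held at 1.
4. Ψⱼⱼ | rest — inverse gamma.
5. (γ, b) | rest — weighted-regression multivariate normal (weights
   1/(k₂²σeᵢ) on the pseudo-response η − k₁e).
6. σ | rest — inverse gamma with shape a₀ + 3n/2 (n exponential terms
   plus n conditional-normal terms).
7. Φ | rest — inverse Wishart.

Each quantile level is fitted independently; crossing of fitted quantile
paths is a reportable diagnostic, not prevented.  Defaults are 2 chains ×
6000 iterations with 2000 burn-in; the test suite and the acceptance
script use 2 × 1800–2500 with 800–1000 burn-in at n = 1000–2000, which
gives split-R̂ < 1.05 and ESS > 100 for the structural coefficients on the
synthetic designs used.  Identical seed and configuration reproduce draws
bit-for-bit.

### Scaling convention

Indicators are z-scored and covariates centred/scaled internally to keep
the fixed priors weakly informative regardless of raw units; all reported
draws are mapped back to the original indicator scale (on which the anchor
loadings are again exactly 1, and γ, b, σ, Φ have their natural units).
In the degenerate "observed factors" mode (each factor read directly from
its anchor column, the Ψ→0 limit) no standardization is applied and a
constant covariate column supplies the intercept; this mode reduces the
sampler to ordinary Bayesian quantile regression and is checked against an
exact linear-programming check-loss minimizer.

### Residual calibration diagnostic

Two summaries of the structural residuals are reported.  The posterior
expectation of the per-draw fraction of negative residuals is calibrated
to τ and is the headline diagnostic.  The sign fraction of the
posterior-*mean* residuals is also reported but is not calibrated off the
median: posterior-mean latent states are shrunk toward the asymmetric
structural prior, which pushes that plug-in fraction toward 0 or 1 at
extreme τ.

## Scoring conventions

* **GHQ-12**: bimodal recoding {0,1}→0, {2,3}→1 summed to 0–12.  The
  instrument's 4-point response scale with a 0–12 total is only consistent
  with bimodal scoring; the 0–36 Likert sum is available as an option.
* **HADS**: plain 0–21 subscale sums, caseness flag at ≥ 8.
* **SLE domains**: item means (not sums), keeping all 11 domains on the
  common 0–5 intensity scale despite unequal item counts (7,5,4,5,4,4,5,
  4,4,2,2); sums are available via the codebook.
* **ERI**: sum(effort) / (c · sum(reward)) with c defaulting to 6/11, the
  effort/reward item-count adjustment; configurable because published
  analyses do not always print it.
* **Missingness**: records missing more than 10 % of instrument items are
  flagged excluded (not silently dropped); smaller gaps are mean-imputed
  within instrument and counted per record.  Downstream stages use the
  complete-case subset.

## Factor analysis

Extraction is principal-component style (eigendecomposition of the
correlation matrix), because "% of total variance explained" is the PCA
quantity; principal-axis iteration is available.  For three equicorrelated
indicators with correlation r the profile factor explains exactly
100·(1+2r)/3 percent — the identity used to calibrate the synthetic
generator.  The number of stressor factors defaults to the eigenvalue>1
rule with the full eigenvalue vector returned as the scree report; varimax
rotation uses Kaiser's pairwise-rotation algorithm with row normalization
(cross-checked in tests against an independent rotation implementation and
a grid-search oracle).  Factor scores use the regression method on
standardized indicators and are rescaled to unit variance.  Quartile
splits use sample quartiles with ties assigned to the lower quartile.

## Synthetic data generator

The generator emulates the data structure the analysis assumes: 14
indicators with the 3/7/4 block pattern, a structural quantile equation
with 12 stylized covariates (age, sex, marital status, two education
dummies, household size, shift work, sleep duration, smoking, BMI, ERI
ratio, physical activity), and a right-skewed structural error.  Default
calibration choices:

* γ = (0.2, 0.8): the personal-stressor domain dominates the
  socioeconomic one, a stylized echo of the motivating analyses.
* Profile indicators equicorrelated at r = 0.6889, so one factor explains
  79.26 % of their variance.
* Stressor indicators with squared standardized loading 0.3355, so the
  two-factor solution explains (2 + 9·0.3355)/11 ≈ 45.6 % of total
  variance (this identity is independent of the factor correlation).
* Structural error: skew-normal with moment skewness 0.9 (shape solved
  numerically), centred so its median is zero; ALD and normal families
  are available, ALD errors centred at their own τ-quantile.
* Latent predictor correlation 0.3.

What the generator does **not** emulate: ordinal/bounded indicator
supports (Likert discretization is opt-in and off by default, because the
fitted model treats indicators as continuous), survey design effects
(cluster/stratified sampling, weights), item-level missingness mechanisms,
and measurement non-invariance.  Passing recovery tests on this generator
therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to those real-data features.

## Classical evaluation

The mean-regression comparison model replaces the ALD by a normal
structural error and is fitted by ML.  Because the covariates are
exogenous with a saturated covariance block, the joint covariance ML
factorises: the optimizer works on the conditional Gaussian likelihood of
the indicators given covariates (quasi-Newton on log-variance/Cholesky
parameterizations, uniquenesses bounded at 1e−6 to handle Heywood cases),
and the stacked model-implied covariance is then assembled with the sample
covariate covariance.  χ² = (n−1)·F_ML; the baseline for CFI/TLI is the
full independence model; RMSEA uses √(max(χ²−df,0)/(df(n−1))).
Acceptability is flagged at RMSEA < 0.10 and CFI, TLI > 0.8.

### Posterior predictive checking

For each retained draw a replicate dataset is simulated from the fitted
model on the observed covariates, and a discrepancy is computed for
observed and replicate data by an identical procedure; p_B is the
proportion of draws with D(y_rep) ≥ D(y_obs).  Three discrepancies are
implemented, and the choice is logged with the result:

* **orthogonality** (default): n·Σ_k corr(δ, ξ_k)² with latent states
  refreshed from their full conditionals at the draw.  Near a χ²₂ scale
  under the model and O(n) under structural misspecification, it is both
  well calibrated (p_B near 0.5 when the model is true) and sensitive
  (p_B collapses to ~0 when a strong structural coefficient is forced to
  zero).
* **complete**: measurement residual χ² + scaled structural check loss +
  the orthogonality term.  Calibrated, but the high-variance residual
  terms dilute power — the ALD scale adapts to absorb structural misfit.
* **moments**: χ²-type lack of fit of the implied conditional first and
  second moments.  Very sensitive, but anti-conservative under the true
  model because the posterior adapts the implied covariance toward the
  observed sample covariance.

These behaviours are measured by the test suite and the acceptance
script rather than asserted; the default was chosen as the only variant
exhibiting both calibration and power on the synthetic designs.

## Study-design utility

`cochran_sample_size(p, alpha, d, round_to)` returns
z²_{1−α/2}·p(1−p)/d², rounded **up** to the next multiple of `round_to`
(p = 0.1, α = 0.05, d = 0.01 → 3457.3 → 3500 at round_to = 100).

## Numerical choices and problem sizes

* All randomness flows from explicit `numpy` `Generator` seeds; the
  pipeline splits one top-level seed per stage via `SeedSequence`.
* The ALD mixture-density quadrature (adaptive Gauss–Kronrod) is required
  to agree with the closed form to 1e−6 and serves as an executable proof
  of the augmentation identity.
* Recovery and concordance checks run at n = 1500–2000 with 2 chains of
  1800–2500 iterations; factor-structure recovery uses 100 replicates of
  n = 1000; the eigenvalue identity uses n = 50000.  These sizes give
  Monte-Carlo error comfortably below the assertion tolerances while
  keeping the full suite at a few minutes on one CPU.

## Known limitations

* No non-crossing constraint across quantiles; paths can cross in small
  samples.
* No ordinal measurement model; heavily discretized indicators will
  attenuate loadings.
* Posterior medians of quantile-regression coefficients differ from the
  exact check-loss minimizer by O(1/n); at n = 200 the gap is typically
  0.02–0.06 on standardized designs.
* Missing-data handling is listwise after the 10 % rule plus simple
  within-instrument mean imputation; no FIML or multiple imputation.
* The mean-SEM optimizer uses numerical gradients; extremely
  ill-conditioned covariate blocks may need rescaled inputs.
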