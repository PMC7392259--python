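# Methods

## The analysis in one paragraph

A balanced MET trial (G genotypes × E environments × r blocks, yields in
kg/ha) is decomposed by a joint fixed-effects ANOVA with blocks nested in
environments; its error mean square (MSR) and grand mean feed the rest of
the pipeline.  Environment quality is the mean-deviation index
`I_j = ȳ·j· − ȳ···`, which sums to zero for balanced data.  Per genotype,
the block-averaged cell means are regressed on `{1, I_j, T(I_j)}` with a
fixed change point at `I = 0`; the Bayesian fit uses conjugate
Normal–Gamma priors and an exact Gibbs sampler, and the frequentist fit
(statsmodels OLS) both stands alone and supplies informative
hyperparameters.  Posterior 95% equal-tailed intervals drive the
adaptability/stability classification; DIC compares prior sets; Geweke and
Raftery–Lewis check the chains.

## Assumptions

* The change point is fixed at index 0 (no Toler-style join-point search).
* Responses for the regression are genotype × environment means over
  blocks, not plot values: the per-genotype likelihood has one Gaussian term
  per environment, and the stability parameter subtracts `MSR/r`, which
  presupposes means over r blocks.
* Errors are homoscedastic within genotype across environments; variances
  differ between genotypes.
* The joint ANOVA treats all effects as fixed for sums of squares and tests
  genotypes, environments and G×E against the error mean square, as is
  conventional in joint MET ANOVA tables — even though environment and
  interaction effects are usually conceptualized as random.  A mixed-model
  expected-mean-square ladder is deliberately not implemented.
* The design must include at least one favorable (`I_j > 0`) and one
  unfavorable environment, otherwise the segmented design matrix is rank
  deficient and the fit is refused (`EstimabilityError`).

## Sampler

All four full conditionals are exact:

* `β_k | rest ~ Normal( (τ·c_k + μ_k/σ²_k) / p_k , 1/p_k )` with
  `p_k = τ·(XᵀX)_kk + 1/σ²_k` and `c_k` the residual cross-product holding
  the other coefficients fixed;
* `τ | rest ~ Gamma(α + a/2, β + SSE(β)/2)` (shape/rate), a = number of
  environments.

Chains start at the least-squares solution, with τ at the implied residual
precision.  Defaults mirror common practice for this model family: 100 000
iterations, 10 000 burn-in, thinning 5, one chain.  A single integer seed
makes a run bit-reproducible; the pipeline derives one seed per
(prior mode, genotype) chain from the top-level seed, all below 2³¹.

### Gamma parameterization

The precision prior is Gamma(shape α, **rate** β), mean α/β.  Under this
convention the vague prior Gamma(0.001, 0.001) has prior mean 1 for the
precision, which is the standard reading of that BUGS-era default.

### How vague is "vague"?

`minimally_informative_priors()` defaults to coefficient variance 1e5, the
value conventional in published analyses of this model family.  That is
vague for slopes but **not** for intercepts measured in thousands of kg/ha:
a N(0, 1e5) prior (SD ≈ 316) shrinks a ~9000 kg/ha intercept hard toward
zero and pushes the sampler into a degenerate large-σ² mode.  Published
vague-prior results in this literature (posterior means essentially equal
to the least-squares estimates) are only obtainable when the prior is flat
relative to the data scale, so the pipeline's M1 mode uses coefficient
variance 1e10 by default (`PipelineConfig.m1_coef_var`); the literal 1e5 is
still available through the function's argument.  Center your responses if
you want 1e5 to be genuinely weak.

### Stability parameter

`σ²_d = σ² − MSR/r` is a method-of-moments subtraction and can be negative
by sampling noise.  Draws are kept untruncated (truncation would bias the
credible-interval test against 0 that the classification uses); a summary
with negative posterior mean carries a flag.

### DIC

`DIC = D̄ + p_D = D(θ̂) + 2 p_D` with `p_D = D̄ − D(θ̂)` (deviance at the
posterior means of β and σ²) — the standard Spiegelhalter form; lower is
better.  The per-genotype comparison reported is
`DIC(vague) − DIC(informative)`, positive when the informative prior helps.

## Prior elicitation (M2)

From the per-genotype OLS fit: prior means are the point estimates, prior
variances `strength × se²` (strength defaults to 1; larger = weaker), and
the precision prior Gamma(shape s, rate s·σ̂²) has mean `1/σ̂²`.  With
strength 1 the prior carries roughly the information of one replicate data
set, which is why M2 intervals are ≈ 1/√2 the width of vague-prior
intervals on the same data.  A noiseless fit (σ̂² = 0) cannot define a
proper precision prior; a configurable floor handles synthetic fixtures.

## Diagnostics

* **Geweke**: compare means of the first 10% and last 50% of the chain;
  each window's variance is a Bartlett-windowed autocovariance sum with
  window width `round(sqrt(n))`.  |z| < 1.96 passes; the pipeline warns but
  does not abort on failure (diagnostics are reported, not gating).
* **Raftery–Lewis** (q = 0.025, r = 0.005, s = 0.95): two-state Markov
  approximation of the indicator chain {draw ≤ q-quantile}; thinning chosen
  by the BIC first- vs second-order test; reports burn-in, required N and
  the dependence factor `(M+N)/N_min`.

These are implemented in-package because no installed Python library
currently ships them.

## Classification rules

Closed-interval containment: an interval endpoint exactly at the reference
counts as "contains" (this is what reproduces published counts where
interval bounds are printed rounded to two decimals, e.g. an upper bound of
exactly 1.00).  Thresholds: R² > 80 (percent, configurable), high mean =
posterior mean β₀ above the trial grand mean.  Recommendation labels:

| β₁ vs 1 | β₁+β₂ vs 1 | high mean | label |
|---|---|---|---|
| below | — | yes | `unfavorable_adapted` |
| equal | above | yes | `improvement_responsive` |
| equal | equal | yes | `general` |
| otherwise | | | `none` |

## Synthetic data

`segstab.simulate` generates balanced trials whose cell means sit exactly
on each genotype's segmented response, plus Normal block effects and
plot-level error:

`y_ijk = β₀ᵢ + β₁ᵢ I_j + β₂ᵢ T(I_j) + b_k(j) + ε_ijk`.

Design choices:

* The environment index is drawn with a guaranteed favorable fraction
  (signs fixed, magnitudes |N(0, env_effect_sd)|, the unfavorable group
  rescaled so the index sums to zero without flipping signs) — the
  segmented design is full rank for every simulated data set.
* Default genotype truths are drawn uniformly (β₀ ∈ [7500, 9500] kg/ha,
  β₁ ∈ [0.4, 1.6], β₂ ∈ [−1, 1], plot-error SD ∈ [700, 1400] kg/ha) and
  then recentred so that mean(β₁) = 1, mean(β₂) = 0 and mean(β₀) equals the
  configured grand mean.  Real data satisfy these constraints identically
  under the mean-deviation index, and recentring makes the realized
  (data-derived) index coincide with the designed one — exactly so in the
  noiseless case — so generation and analysis share one index definition.
* Default magnitudes (grand mean 8683 kg/ha, environment-effect SD 1500,
  block SD 300, reference dimensions 25 × 22 × 2) mimic a realistic
  tropical maize hybrid trial; they are illustrative, not inferential.

What the simulator does **not** emulate: missing plots and unbalanced
designs, spatial field trends, genetic correlation between hybrids,
heteroscedasticity across environments, and cell-mean deviations from the
segmented surface (simulated genotypes have true σ²_d ≈ 0).  Passing
recovery tests on these data therefore validates the estimation machinery,
not the adequacy of the segmented model for any particular real trial.

## Problem sizes used in the checks

The test suite and the acceptance script run desk-scale versions of every
study: chains of 3 000–20 000 iterations, 5-genotype × 22-environment
synthetic trials, 50 replicate fits for coverage, and one full-pipeline run
at the reference 25 × 22 × 2 dimensions.  These sizes were chosen so the
whole suite completes in minutes on a laptop while keeping Monte Carlo error
well inside the asserted tolerances; the library defaults remain the full
100 000-iteration settings.

## Known limitations

* No estimated change point, t-errors, or hierarchical pooling across
  genotypes.
* Unbalanced data are accepted for index/means (with available
  observations) but refused by the joint ANOVA, so the stability parameter
  requires a balanced trial.
* DIC differences between prior sets depend directly on the elicitation
  strength; they are a relative, not absolute, measure of prior usefulness.
* The two checks against the published maize trial's plot-level data run
  only when the user supplies the deposited spreadsheet
  (`data/maize_met_yields.xlsx`); it is not redistributed with the package.
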