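# Methods

## Model and estimands

All candidates are Gaussian linear models y = Xβ + ε, ε ~ N(0, σ²Iₙ),
fitted by maximum likelihood: β̂ = (XᵀX)⁻¹Xᵀy and σ̂² = RSS/n. The MLE
denominator n (never n − p) is load-bearing: the closed-form discrepancy
below is derived under the MLE. The parameter count of a candidate is
k = (number of regression coefficients, intercept included) + 1, counting
the error variance as the AIC convention does. Only the difference k₂ − k₁
enters the corrected comparison probability, so a convention that shifted
both candidates' counts equally would change reported BDk values but not
BDCPk.

The Kullback–Leibler discrepancy of fitted parameters θ̂ = (β̂, σ̂²) against
the truth g is d(g, θ̂) = E_g[−2 ℓ(θ̂ | y)]. When the truth is itself linear
with conditional mean Xβ₀ and error variance σ₀², the discrepancy
conditional on the design is

    d(g, θ̂) = n log(2πσ̂²) + n σ₀²/σ̂² + ‖Xβ₀ − Xβ̂‖² / σ̂².

Because the candidate is Gaussian, the expectation depends on the error law
only through its first two moments; the same formula therefore serves the
Student-t and normal-mixture scenarios with σ₀² = Var(ε) (5/3 for t₅,
0.85·1 + 0.15·50 = 8.35 for the mixture). The candidate's fitted mean Xβ̂
uses its own columns; the true mean Xβ₀ is always the full-truth conditional
mean on the same rows, so omitted covariates show up as mean mismatch.

## Bootstrap engine

The bootstrap distribution of the discrepancy uses the plug-in principle
throughout: the empirical distribution ĝ replaces g, a case resample
(rows (yᵢ, xᵢ) drawn jointly with replacement) replaces y, and the resample
MLE θ̂* replaces θ̂, giving d(ĝ, θ̂*) = −2 ℓ(θ̂* | y) evaluated on the
*original* data. Case resampling (rather than residual resampling) is the
implemented and only mode: the scenarios treat the covariates as random, and
case resampling is the plug-in principle applied to their joint
distribution with the response.

Both candidates are refit on the **same** resample, preserving the joint
distribution of their discrepancies; the index vector of every resample is
stored, so any replicate can be replayed exactly. Each replicate draws its
indices from its own child stream of the root seed (`SeedSequence.spawn`),
so enlarging J extends the replicate set without perturbing earlier
replicates. Seeds are mandatory everywhere — an unseeded resampling run is
treated as an error, not as a convenience default.

Degenerate resamples — rank-deficient resampled design or numerically zero
residual variance (relative floor 10⁻¹² on the mean-square response) — are
rejected and redrawn from the same replicate's stream, because a plug-in
discrepancy at σ̂*² → 0 is −∞ and would poison the replicate set. The
rejection count is surfaced on the result for audit and the engine aborts
(naming the worse-behaved candidate) if total attempts exceed 10·J. With
continuous covariates rejections are rare; they matter only for tiny n or
near-collinear designs. Resample fits are solved in batch via the normal
equations (the per-replicate Gram matrices are tiny and well-conditioned at
the simulated design scale); the original-data fit uses a rank-revealing
least-squares solve and refuses rank-deficient designs outright.

Ties in the indicator comparisons are resolved by strict inequality. For
continuous data ties are probability-zero; for integer-valued toy data this
makes "identical candidates" deterministically report probability 0 rather
than 1/2.

## Corrections

kb = J⁻¹ Σⱼ −2 ℓ(θ̂*⁽ʲ⁾ | y) − (−2 ℓ(θ̂ | y)) is computed per candidate from
the same replicates used for the comparison (no extra resampling cost), and
BDb = BD + kb ≡ 2·BD − (−2 ℓ(θ̂ | y)) — both algebraic forms are computed
and tested for equality. For an adequately specified candidate at large n,
E*[−2 ℓ(θ̂* | y)] ≈ AIC − k, which makes kb a consistent stand-in for k;
the test suite checks the dataset-average of kb against k at n = 500.

## Simulation scenarios

Six scenario sets cover the comparison settings of interest. In every set
the truth is yᵢ = xᵢᵀβ₀ + εᵢ with covariates drawn independently as
N(μⱼ, 100); the entries of μ are ±1 with equal probability, drawn **once
per scenario** and then fixed, while the design itself is redrawn for every
dataset. (Redrawing μ per dataset would make the truth-based KLDCP a mixture
over designs; the fixed-μ reading matches the scenario definitions.) Sets
5–6 instead give the alternative a single spurious covariate x2 ~ N(1, 100).

| set | truth (β₀ beyond intercept 1) | errors | null vs alternative |
|---|---|---|---|
| 1 | 0.5, 0.5 on x2, x3 | N(0, 50) | correct vs + x4…x7 |
| 2 | 0.11, 0.13, 0.12, −0.11 on x2…x5 | N(0, 45) | drops x5 vs correct |
| 3 | 0.5, 0.5, −0.5, −0.5, 0.1 on x2…x6 | N(0, 50) | {x2,x3} vs {x4,x6} |
| 4 | 0.5, 0.5, −0.5, −0.5, 0.5, 0.5 on x2…x7 | N(0, 50) | {x2,x3} vs {x4,x5} |
| 5 | intercept only | t₅ (σ₀² = 5/3) | intercept vs + x2 |
| 6 | intercept only | 0.85·N(0,1) + 0.15·N(0,50) (σ₀² = 8.35) | intercept vs + x2 |

Covariates that exist only to overspecify a candidate are generated per
dataset and live in the same dataset object, so both candidates always see
identical rows. Set 6 defaults to J = 500 resamples (the mixture's heavy
tail inflates bootstrap variance); all other sets default to J = 200.

Two estimands are reported per scenario. The truth-based **KLDCP** is the
proportion of freshly simulated datasets on which the fitted null's
closed-form discrepancy is strictly smaller than the alternative's; it is
computed in independent batches (defaults: 10 batches of 1000 draws) whose
spread gives its Monte-Carlo error. The bootstrap quantities (BDCP, BDCPk,
BDCPb, and per-candidate E(KLD), E(BD), and the post-correction biases
ΔBDb, ΔBDk) are averaged over R simulated datasets.

## Problem sizes and numerical choices

Package defaults run the harness at R = 500 datasets, J = 200 bootstraps
and 10 × 1000 KLDCP draws — roughly a tenth of the published study's
5000 / 200 / 100 × 5000 — which reproduces the published means to well
within Monte-Carlo error (about ±0.013 on a probability near 0.5 at
R = 500) while keeping a full scenario run in seconds. The acceptance
script uses the same sizes; full scale is a config change away.

Summary tables round to 3 decimals. Scenario SDs use the n−1 denominator
and are reported as null (undefined) when only one replicate exists.
Comparison results serialize to JSON with the package version, seed, J and
the resample-rejection count, and every CLI run writes a manifest
sufficient to regenerate its outputs exactly.

## What the generators do and do not emulate

The synthetic scenarios exercise model *structure* misspecification
(omitted/extra covariates) and error-law misspecification (heavy tails,
scale mixtures) under independent rows and exogenous continuous covariates.
They do not emulate dependent observations, discrete or collinear
covariates, heteroscedasticity, or mean-model nonlinearity — passing tests
say nothing about those regimes. The comparison engine itself makes none of
the scenarios' assumptions beyond i.i.d. rows, but its Gaussian likelihood
is the likelihood being compared: with strongly non-Gaussian responses the
discrepancy being estimated is still the KL discrepancy to the Gaussian
approximation.

## Known limitations

* Gaussian linear candidates only; the operation contracts would extend to
  GLMs but no other family ships.
* Nonparametric case bootstrap only — no residual or parametric bootstrap.
* No confidence intervals for the comparison probabilities themselves; the
  scenario harness reports their across-dataset spread instead.
* Single-process execution; the per-dataset loop is embarrassingly parallel
  but parallelism is left to the caller.
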