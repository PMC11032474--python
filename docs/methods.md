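# Methods

This note documents the statistical models implemented in `cmpaths`, the
design of the synthetic-data generator, numerical choices, and known
limitations.  It is written for users who want to understand exactly what
the package computes and what passing its tests does and does not show.

## 1. The path-model estimator (`cmpaths.sem`)

### Model class

Recursive observed-variable path models: a directed acyclic graph over
named variables, a free coefficient per edge (matrix **B**), strictly
diagonal residual covariance **Ψ** for endogenous variables, and a
saturated covariance block for exogenous variables.  No latent variables,
no ordinal endogenous variables, no missing-data (FIML) estimation.
The model-implied covariance is

    Σ(θ) = (I − B)⁻¹ Ψ* (I − B)⁻ᵀ

where Ψ* carries residual variances and the exogenous block.  The
canonical models are the four-variable model (5 paths, df = 1), the
brain-inclusive *full* model (8 paths, df = 2) and *sparse* model
(6 paths, df = 4).  A deliberate structural choice: the BMI↔AT residual
covariance is omitted, which is what makes the four-variable model
over-identified (df = 1) rather than saturated.  Degrees of freedom are
unique moments p(p+1)/2 minus free parameters; "parameter counts" quoted
for model comparison count directed paths only.

### Estimation

θ̂ minimizes F_ML(θ) = ln|Σ(θ)| + tr(S Σ⁻¹(θ)) − ln|S| − p.  For this
model class the minimizer is available in closed form: per-equation least
squares of each endogenous variable on its parents (with the exogenous
block copied from S).  The implementation uses that warm start, then runs
BFGS with the analytic gradient (tolerance 1e-10 on the gradient norm,
maximum 500 iterations) purely as verification — the iteration count is
normally zero.  A fit whose gradient norm exceeds 1e-8 raises an error
carrying diagnostics rather than returning silently.  S must be positive
definite and n must exceed the number of variables.

By default the pipeline fits the correlation matrix of z-scored
residualized variables, so raw and standardized coefficients coincide.
Mean structure is ignored throughout: variables are nuisance-residualized
and centred upstream.

### Inference

* Naive covariance: (ΔᵀWΔ)⁻¹/n with Δ = ∂vech(Σ)/∂θ (analytic) and
  W = ½ Dᵀ(Σ̂⁻¹ ⊗ Σ̂⁻¹)D.
* Robust (sandwich/Huber–White): (ΔᵀWΔ)⁻¹ ΔᵀW Γ WΔ (ΔᵀWΔ)⁻¹ / n with Γ
  the empirical covariance of vech(z zᵀ) over rows — per-row data is
  therefore required, moments alone do not suffice.
* Wald z is the estimate divided by its robust SE (exactly, by
  construction), with two-sided normal p-values.  Two-sided parametric
  inference is used for indirect effects as well, on the grounds that
  products of coefficients are asymptotically normal at these sample
  sizes; no bootstrap is implemented.
* Scaled test statistic: T_SB = T_ML / c with c = tr(UΓ)/df,
  U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW, and T_ML = n·F̂.  For a saturated model the
  scaling is undefined; the package reports T_SB = 0 with c = 1 and a
  warning.  A calibration fact worth knowing: c responds to *joint*
  (common-scale-mixture) heavy tails.  With independent heavy-tailed
  residuals the constrained moment direction of the four-variable model
  is a product of independent residuals — fourth-moment free — and c
  correctly stays near 1; the test suite verifies both regimes.

### Fit indices

CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, 0) against the independence
baseline (no edges, no covariances); noncentrality estimates below 1e-8
are floored at zero so saturated models report CFI = 1 despite floating
residue.  RMSEA = √(max(T−df,0)/(df·n)) with a 90% noncentral-χ²
confidence interval solved by root finding.  SRMR is the RMS of the
standardized residual moment matrix over unique elements including the
diagonal.  Robust CFI/RMSEA plug the scaled statistics of both models
into the same formulas; the population-corrected robust-RMSEA family is a
known alternative and is intentionally not asserted as equivalent.
Qualitative bands: CFI good > 0.97, acceptable 0.95–0.97; SRMR good
< 0.05, acceptable 0.05–0.10; RMSEA good < 0.05, acceptable 0.05–0.08.

### Nested comparison

Scaled difference statistic with correction
cd = (df₀c₀ − df₁c₁)/(df₀ − df₁) (0 = sparse, 1 = full), referred to χ²_k
with k the difference in path counts.  cd can be negative in finite
samples; the package then falls back to the unscaled difference with a
logged warning, never a silently negative statistic.  Type-I error of the
scaled test is verified by simulation (2,000 sparse-true replicates at
n = 2,000) in the acceptance suite.

## 2. The synthetic generator (`cmpaths.synth`)

### What it emulates

A UK-Biobank-like cohort: right-skewed questionnaire sum scores for CM
and AT (integers in [0, 25], zero-inflated), lognormal BMI and CRP,
age/sex/SES/site covariates with modest effects, and a parcellated brain
with smooth effect maps.  Raw-scale marginal defaults (mean, SD): BMI
(26.5, 4.2), CRP (2.03, 3.53), CM (1.70, 2.31), AT (1.93, 2.37) for the
imaging-subsample configuration; the replication configuration uses the
full-cohort values (BMI 26.8/4.6, CRP 2.29/4.02, CM 1.76/2.41, AT
2.09/2.51) and a direct CM→CRP coefficient of 0.0095 instead of 0.008.

### The structural contract

The structural equations are defined on the scale the analysis actually
fits: z-scored, covariate-residualized log (or log1p) values.

* CM is generated first as a calibrated count (below); its z-scored,
  design-residualized log1p score is the structural driver.
* BMI and CRP are lognormal, hence exactly log-linear in their latent
  scores: configured coefficients are recovered exactly (up to sampling
  noise).
* AT is an endogenous *count*, and counts are where care is needed: the
  observed log1p score is a staircase function of the latent, which
  attenuates any path into it by a factor ≈ 0.95.  The generator corrects
  for this *a priori*: the latent CM→AT coefficient is solved by exact
  quadrature over the known (CM-atom × AT-count) grid so that the
  observed-scale coefficient equals the configured a3.  No sampling is
  involved in the correction and it is independent of any generated data.
  The CRP equation then uses the *observed* standardized AT, so a2, b1
  and b2 hold exactly by construction.
* Residual SDs default to the unit-variance completion (so standardized
  variables have variance one and coefficients are directly standardized
  betas); explicit values, including zero, can be configured.

Count marginals use a rounded-lognormal quantile map
count(x) = clip(round(expm1(μ + σx)), 0, 25) whose two parameters are
solved exactly against the target raw mean/SD; the zero inflation arises
from rounding the small-value tail down to zero (35% zeros for the CM
defaults, matching the heavy skew the log transform must handle).

Covariate effects are injected on the log/latent scale *before*
exponentiation or count mapping, scaled so total variance stays one
(hence marginal calibration is unaffected).  This makes the analysis
pipeline's residualize-after-log order exactly right in the synthetic
world.  CM's covariate dependence defaults to zero — the joint
distribution of maltreatment and demographics in the real cohort is not
documented, so it is exposed as a configurable vector rather than
guessed.  A caveat follows: nonzero covariate effects on the *count*
phenotypes interact with the discretization, so coefficient recovery
through counts is exact only up to a second-order term in the covariate
R² (≈ 0.03 by default for AT — empirically invisible at the tested
sample sizes).

### Brain maps

Cortical parcels are a Fibonacci lattice on the unit sphere (a stand-in
geometry with quasi-uniform parcel spacing); the seven subcortical
structures carry no coordinates and are exempt from spin tests.  Each
region's standardized value is c1·BMI + c2·CRP + c3·AT plus Gaussian
noise; cortical noise and the cortical effect maps are smooth fields
drawn from a squared-exponential kernel in chordal distance
(k(d) = exp(−d²/2ℓ²), default ℓ = 0.3; ℓ = 0 gives independent noise).
The BMI and CRP maps are two noisy copies of one shared smooth map
(mixing weight 0.9), reproducing the highly correlated immuno-metabolic
map regime; the AT map is weak cortically (amplitude 0.01, mixed with the
negated shared map) and constant negative subcortically (−0.04), with
BMI +0.02 and CRP −0.03 subcortically — the qualitative pattern of
positive metabolic and negative trauma/inflammatory subcortical effects.
Effect amplitudes (±0.01–0.04 standardized) were chosen once as realistic
for population neuroimaging; per-region residual SDs complete variance to
one.  Raw scales are thickness-like (2.60 ± 0.15 mm) cortically and
volume-like (structure-specific means, 10% SD) subcortically.

### What it does not emulate

No raw images or surfaces; no genuinely bilateral (pre-symmetrized) data
by default; no informative missingness (only optional MCAR); no site
effects beyond a mean shift; phenotype distributions are smooth
transforms of Gaussians rather than mixtures of subpopulations.  Passing
tests therefore demonstrate correctness of the *statistical machinery*
under the assumed generating process, not robustness to the messiness of
real cohort data.

## 3. Preprocessing (`cmpaths.preprocess`)

Log conventions: plain natural log for strictly positive BMI and CRP;
log1p for the questionnaire sums, which contain zeros (the choice is a
recorded config switch, not an assertion about how any particular study
handled zeros).  Outlier screening excludes regional values more than
5 raw MADs from the regional median — no 1.4826 normal-consistency
constant (exposed as an option); a zero MAD excludes nothing.  Nuisance
regression uses ordinary least squares on age, sex, age×sex, SES for
phenotypes, plus site indicators for regional measures; residuals are
exactly orthogonal to the design and missing cells stay missing.
Bilateral homologs are averaged; if one side is excluded the other side's
value is used alone (maximizing retained data; the drop-the-cell
alternative is configurable by masking beforehand).  Variables are
z-scored after residualization.  Residualization is idempotent and the
whole chain commutes with row permutations.

## 4. Brain-map statistics and the spin test

Region-wise models are simple (one-predictor) regressions by design —
the three adult variables are deliberately not adjusted for each other
at this stage.  Regions with fewer than 10 complete cases or numerically
constant values (relative variance < 1e-14) are reported missing, not
zero.  Multiplicity: BH step-up FDR at 5% over the analysed-region family
by default (missing regions drop out of the family and this is logged);
Holm step-down is available where familywise control is wanted, and the
orchestrator records which was used.  The H3 model contrast defaults to
FDR, with Holm as the documented stricter alternative.

Spin test: uniformly random SO(3) rotations (Haar measure via
`scipy.stats.special_ortho_group`), default S = 10,000 spins.  For each
spin, every target parcel takes the value of the source parcel whose
rotated centroid lies nearest to the target's original centroid — this
direction of nearest-neighbour query guarantees every parcel is assigned
a value; assignments may duplicate or drop values, as is standard for
centroid-level spin tests (a documented divergence from vertex-level
implementations).  Because maps are bilaterally symmetrized, a single
hemisphere-sphere is rotated with no mirroring step.  The two-sided
p-value is (1 + #{|null| ≥ |observed|})/(S + 1), so p ∈ [1/(S+1), 1];
one- vs two-sided and S are package defaults, not attributions to any
particular study.

## 5. Orchestration

`run_h1` refuses n < 100 (asymptotic inference unreliable), reports the
Spearman correlation matrix, robust fit and indices, both indirect
effects, and the single-predictor CRP-on-CM regression.  `run_h3` fits
both models per region on that region's complete cases, compares them
with the scaled LR test, assigns the winner (full where the corrected
test rejects, else sparse), leaves non-converging or under-sampled
regions explicitly unevaluated, and estimates each indirect chain only
inside its host model's winning set, with FDR within each chain's
evaluated set.  Subcortical regions are excluded from spin tests but
included in regressions and path models.  For the figures' convention of
reporting indirect effects, the delta-method z of the product is the
primary statistic (the per-component z's are available from the fit
table).

End-to-end determinism: every stage derives its randomness from the
configuration seed (sub-streams per stage), and identical configurations
reproduce identical outputs to 1e-10 across runs.

## 6. Problem sizes used in tests

Simulation-based tests are sized for a single CPU: parameter recovery
uses ten cohorts at n = 21,738 and ten at n = 116,887; the structural
consistency check uses one cohort at n = 100,000; marginal calibration
n = 50,000; LR type-I calibration 2,000 replicates at n = 2,000 with a
3-region brain; spin calibration 500 runs at S = 500; designed H3
recovery experiments use n = 20,000 with 12-region geometries.  The full
suite runs in under two minutes.

## 7. Known limitations

* Estimation treats the correlation matrix as a covariance matrix
  (standard practice in this analysis class); SEs of variance-adjacent
  parameters carry the usual correlation-metric caveat.
* The robust-RMSEA/CFI variants are the scaled-statistic plug-in family;
  population-corrected variants differ slightly.
* The centroid spin test is approximate for parcels of unequal size.
* The generator's attenuation correction is exact for the default
  (covariate-free) CM count distribution; strong covariate effects on
  the count phenotypes would re-introduce a small bias.
* Cross-sectional path models support no causal claims; the package
  quantifies agreement between a hypothesized directed structure and an
  observed covariance matrix, nothing more.
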