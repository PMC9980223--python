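# Methods

## Generative model for trio cohorts

`triomr.simulate` draws, for each of `n_couples` families and `n_snps`
independent biallelic loci:

1. **Parental genotypes.** Dosages Binomial(2, f_j), independently per
   person and locus; frequencies f_j strictly inside (0, 1).
2. **Assortative mating.** Each parent receives a latent score
   a = φ·z(g) + (1−φ)·v, where z(g) is the *standardized* mean dosage
   across loci and v ~ N(0,1).  Mothers and fathers are sorted on their
   scores and matched rank to rank, so φ = 0 gives random mating and
   φ = 1 sorts on genotype alone.  Standardizing g before mixing puts the
   genotype and noise components on a common scale so that φ interpolates
   meaningfully; with it, the spousal genotype correlation rises smoothly
   and monotonically in φ.  Rank-order pairing was chosen as the simplest
   mechanism with that property; a Gaussian-copula pairing would produce
   a smoother joint distribution at the same rank correlation and could
   be swapped in behind the same interface.
3. **Transmission.** At each locus the child receives one allele drawn
   uniformly from each parent's pair: a parent of dosage d transmits the
   effect allele with probability d/2.  This enforces Mendelian legality
   by construction (checked exactly by `TrioCohort.validate_transmission`)
   and gives E[g_child | parents] = (g_m + g_f)/2 — the source of the
   ≈0.5 parent-to-child regression coefficients.
4. **Phenotypes.**  Parental exposure x_p = g_p·w + ε_p with
   ε_p ~ N(0, σ_x²); child outcome
   y = β_m x_m + β_f x_f + d·(g_c·w) + g_c·α + ε_y,
   α_j ~ N(μ_α, σ_α²), ε_y ~ N(0, σ_y²).

Defaults (w = 1, β_m = β_f = 1, d = 0, α ≡ 0, σ_x = σ_y = 1, one locus)
reproduce the classic one-SNP dynastic-effect simulation: exposure =
genotype + standard normal noise, outcome = sum of both parents'
phenotypes + standard normal noise.  The per-parent coefficient of 1 is
read as "each parent's phenotype enters with coefficient 1"; the
alternative reading (coefficient 1 on the parental sum) is the same model
here since β_m = β_f.  Multi-locus simulation, direct effects and
per-variant pleiotropy generalize that base model so the summary-data
estimators and the child-PGI conditioning claim can be exercised; their
defaults switch them off.

Randomness flows from one root seed through named per-stage child streams
(`parental_genotypes`, `assortment`, `transmission`, `pleiotropy`,
`exposure_noise`, `outcome_noise`), so identical configurations are
bit-reproducible and changing the variant count does not perturb the
phenotype noise.

**What the generator does not emulate:** linkage disequilibrium between
simulated loci (the clumping tests build their own LD fixture from
correlated reference dosages), phenotypic rather than genotypic
assortment, sibling or grandparental structure, missing data, and
population stratification.  Passing tests therefore demonstrate estimator
behaviour under the stated model, not robustness to those real-data
features.

## Polygenic indices

Clumping is the standard greedy procedure: discard variants above the
p-value threshold (default 5×10⁻⁸), walk the rest in ascending p-value
order (ties broken by chromosome, position, variant id, making the output
invariant to input row order) and keep a variant only if every kept
same-chromosome variant within the window (default 10,000 kb) has
r² below the threshold (default 0.01; the two-sample workflow
conventionally uses a stricter 0.001).  r² comes from an empirical
reference dosage matrix (`LdReference`); a missing r² for an in-window
pair is an error, never silently treated as independence.  PGIs are
weighted dosage sums, standardized within the supplied sample and per
role (mother/father/child separately), matching the per-SD reporting
convention.

A note on the transmission coefficient: the joint regression of the raw
child PGI on both raw parental PGIs has coefficients of exactly ½ in
expectation at *any* assortment level.  On standardized scores the
coefficient is ½·SD(parent PGI)/SD(child PGI), and assortment inflates
the child-score variance (via the spousal covariance term), shrinking the
standardized coefficient below ½ (≈0.43 at φ = 0.6 in our simulations).
Reported values of ≈0.498/0.496 on standardized indices are consistent
with the weak spousal PGI correlation seen empirically, so the headline
reproduction simulates under random mating.

## Individual-level estimators

All fits share one linear-algebra core (QR least squares via
`numpy.linalg.lstsq`) and a CR0 cluster-robust sandwich with a
G/(G−1) finite-sample factor, clusters = families ("robust and clustered"
is the only constraint inherited from the design; CR0×G/(G−1) is the
simplest standard choice and is oracle-checked against statsmodels'
cluster covariance in the tests).  Confidence intervals use ±1.96·SE.

* `fit_phenotypic_ols` — y on x_m, x_f (+ covariates), one joint fit.
* `fit_wf_mvmr` — 2SLS with instruments (g_m, g_f), exposures (x_m, x_f),
  and the child score plus covariates exogenous in both stages.  Second-
  stage residuals for the sandwich are computed with the *observed*
  exposures, the standard correction for the 2SLS variance.
* `fit_standard_mr` — the same with the child score removed everywhere;
  biased when the child's own genotype affects the outcome.
* `fit_single_parent_ols` / `fit_single_parent_mr` — one parent at a
  time, no child score.  These are the conventional analyses that
  assortative mating biases: the omitted spouse's exposure correlates
  with the modelled parent's exposure (OLS) or score (MR), violating
  exogeneity/exclusion.  The bias grid uses these as its "ols" and
  "standard_mr" arms, since the mutually adjusted two-exposure versions
  are already immune to pure assortment (they become biased only through
  direct genetic effects, which the within-family estimator alone
  withstands).

Rows with any missing value are rejected at design assembly (no
imputation); rank-deficient designs raise an error naming the collinear
columns; an instrument matrix with rank below the number of exposures
raises an under-identification error.

**Instrument strength.**  `conditional_f_statistic` implements the
Sanderson–Windmeijer auxiliary-regression procedure for multivariable IV:
2SLS of exposure k on the other exposure (using the full instrument set),
then an F-test of the excluded instruments in the regression of the
residual on instruments + exogenous variables, with the numerator degrees
of freedom reduced by the number of other exposures.  With a single
exposure it reduces to the ordinary excluded-instrument F (oracle-checked).
A numerically zero unrestricted residual sum of squares (instrument ≡
exposure) reports F = ∞.  The companion partial R² is the incremental R²
of the exposure's own instrument given the child score, the other
instrument and covariates.

## Summary-data estimators

Exposure-side associations come from a GWAS summary file; outcome-side
associations are per-variant fits of y on (g_child, g_mother, g_father,
covariates), keeping the requested parent's coefficient with a
family-clustered SE — mutual adjustment removes the transmission path and
the other parent.  Monomorphic variants are dropped with a warning.
Harmonization aligns effect alleles (sign-flipping the outcome beta for
swapped alleles, accepting strand complements) and drops palindromic
variants with effect-allele frequency in (0.42, 0.58), the common
convention for unresolvable strand ambiguity.

With harmonized per-variant pairs (β_xj, β_yj) and w_j = 1/SE(β_yj)²:

* **IVW**: slope Σw β_x β_y / Σw β_x² — the zero-intercept weighted
  regression; SE scaled by max(1, Q/(k−1)) (multiplicative random
  effects with the residual scale floored at 1, the conservative default
  when the fixed/random choice is not dictated); Cochran's Q reported.
* **MR-Egger**: the same regression with a free intercept, exposure betas
  oriented non-negative; the intercept estimates directional pleiotropy
  and carries a t-test (k−2 df) with the same multiplicative-floor
  variance; calibration of that test at the 5% level is verified by a
  200-replicate null simulation.
* **Weighted median**: interpolated weighted 50th percentile of the Wald
  ratios β_y/β_x, weights β_x²/SE(β_y)² (first-order inverse ratio
  variance); SE by seeded parametric bootstrap (default 1,000 draws of
  the summary statistics from their sampling distributions).
* **Weighted mode**: argmax of the weight-scaled Gaussian-kernel density
  of the ratios on a 2,048-point grid padded by 3 bandwidths; bandwidth =
  factor × 0.9 × (weighted MAD × 1.4826) × k^(−1/5), factor default 1;
  bootstrap SE as for the median.

Every estimator reduces to the single-instrument Wald ratio when handed
one variant.  The weighted median's 50%-breakdown property is exact in
the vanishing-noise limit; with finite ratio noise and one-sided
pleiotropy just under the bound, percentile interpolation leaves a small
finite-sample bias, so the noisy-regime test asserts "much less biased
than IVW" rather than exact recovery.

## Bias grid

`run_assortment_grid` crosses φ (default 0, 0.1, …, 0.9 — the grid step
is a convention; only the endpoints matter qualitatively) with seeded
replicates; each cell simulates a cohort and fits single-parent OLS,
single-parent MR and within-family MR.  Per-replicate estimates are kept
so the aggregation (mean, bias = mean − truth, Monte-Carlo SE = SD/√reps)
is re-derivable; estimator failures are logged and excluded, not fatal.
Test-suite scale is 200 replicates of 4,000 couples, which resolves the
contrast sharply (single-parent biases of +0.3 to +1.0 at φ = 0.9 against
Monte-Carlo SEs of ~0.01); the acceptance script uses 200 replicates of
40,000 couples for the headline number.

## Numerical conventions and edge cases

Tab-delimited canonical dialect, 6 significant digits, `NA` for missing.
Hard-call dosage files accept only {0, 1, 2} unless imputed dosages are
explicitly allowed (then any real in [0, 2]).  Zero-variance PGIs
standardize to 0 with a warning.  An empty cohort (n = 0) is valid and
passes transmission validation vacuously.  Latent assortment scores for a
monomorphic panel fall back to pure noise.  Clumping tie-breaks and the
bootstrap/mode seeds make every code path deterministic under a fixed
seed.

## Limitations

Estimation assumes linear, homogeneous effects and complete trios.  No
weak-instrument-robust inference, no LD-aware multi-variant simulation,
no sibling/grandparent designs, no selection or participation bias
modelling, and no missing-data machinery; real-data covariate sets
(principal components, genotyping batch, etc.) enter only as generic
covariate columns.
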