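# Methods

`scoremr` implements a score-based Mendelian-randomization (MR) analysis for
a circulating protein biomarker — modelled on FGF-23 and cardiovascular
disease — together with the synthetic data-generating process needed to test
every stage without access to restricted cohort data.  This note documents
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic generator does and does not emulate.

## The causal model

Genetic variants `G_j` (dosages 0–2) influence a latent log-scale exposure
`X` (units: SDs of the log-biomarker); `X` may influence a binary outcome
`Y` on the logistic-liability scale; a confounder `U` ("kidney function")
may point at both; variants may carry direct (pleiotropic) outcome effects
`α_j` that violate the exclusion restriction:

    X_i = Σ_j β*_j G̃_ij + c_U U_i + ε_i,          G̃ standardized dosage
    P(Y_i = 1) = expit( a₀ + θ X_i + c_V U_i + Σ_j α_j G_ij )

`θ` is the causal log-odds ratio per 1 SD of log-exposure — the estimand all
estimators in the package target.  Var(X) is normalized to 1, so `Σ β*²` is
the fraction of exposure variance explained by genotype (the instrument
R²).

## Synthetic cohorts

**Genotypes.**  Hard calls at Hardy–Weinberg proportions.  Linkage
disequilibrium is generated by a Gaussian copula: a latent normal per
variant, satellites built as `ρ·Z_lead + √(1−ρ²)·ξ`, each latent thresholded
at the HWE cut points.  Thresholding attenuates correlation, so the latent
`ρ` is calibrated numerically (bivariate-normal rectangle probabilities +
Brent root-finding, cached) so the *realized dosage* r² matches the target.
This reproduces pairwise r² without a coalescent simulator; it does not
produce realistic haplotype block structure, recombination maps, or
frequency spectra, and none of the analyses here need them.

**Exposure calibration.**  Planted standardized effects are rescaled by a
common factor per group (cis / non-cis) so the theoretical genetic variance
equals the target R² (defaults 6.3% total, 0.4% for the two cis variants —
the instrument strength of the motivating study); the residual SD is then
chosen so Var(X)=1.  Effects are reported back per allele.

**Censoring.**  The validation biomarker adds Gaussian measurement noise
(default SD 0.3) and flags exactly `floor(n·q)` values below the empirical
`q`-quantile as under the assay's limit of detection (default q = 0.59,
matching the validation cohort the design emulates; ties broken
deterministically by value then row order).

**Outcomes.**  The liability intercept `a₀` is found by Brent root-finding
on the realized cohort so the mean event probability equals the target case
fraction to 1e−6 — exact at any effect size, unlike analytic
approximations.  Default case fractions are the study's: 26,266/337,448
(atherosclerotic) and 12,652/337,448 (nonatherosclerotic).

**Seeds.**  Every operation takes an explicit seed; a cohort spawns
per-stage generators (genotypes / covariates / exposure noise / measurement
/ outcome) from one `SeedSequence`, and the pipeline derives per-stage seeds
from the master seed by fixed offsets, so identical (config, seed) gives a
bit-identical cohort and report.

## The two packaged study configurations

A six-percent total R² spread over 34 loci at n ≈ 19,000 puts every single
variant's expected association statistic (z ≈ 6) at the boundary of a
P < 5×10⁻⁶ screen — real instrument sets are *post-selection* objects, so a
single generated cohort cannot robustly exhibit both "exactly 34 loci pass
the threshold" and "the set explains 6.3%".  The package therefore ships
two configurations built on one 34-variant table:

* **discovery fixture** — strong planted effects (≈1% of variance each),
  two LD satellites per locus (r² ≈ 0.6 within 50 kb), and a correlated cis
  pair (r² = 0.08, 80 kb apart, both within 100 kb of the gene TSS).  Used
  to exercise selection, clumping (satellites absorbed, the
  nearby-but-uncorrelated cis pair kept as separate leads — PLINK
  semantics), and cis flagging.
* **calibrated cohort** — the same 34 leads rescaled to R² = 6.3%/0.4%.
  Used for score validation, covariate balance, association testing, and
  power.  Optionally genotyped at the full locus panel (satellites
  included) so a score built on any clump representative can be computed.

The variant table is synthetic throughout; seven real rsids are retained
only so that consortium-coverage bookkeeping (which instruments each
outcome panel lacks: 4 for the stroke-type panel, 5 for the heart-failure
panel, leaving 30 and 29) matches the worked examples.

## Derivation, score, validation

Per-variant GWAS uses additive linear models adjusted for covariates,
computed by Frisch–Waugh–Lovell residualization vectorized across variants
(identical to per-variant multiple regression; unit-tested against
statsmodels OLS) with normal-approximation p-values — indistinguishable
from t at these sample sizes.  Genomic control is
`λ = median(χ²₁)/0.4549`; on the pipeline's mixed panel (planted loci plus
a null background) λ sits slightly above 1 by construction, since the
signal fraction is far larger than in a genome-wide screen.

Clumping is greedy in ascending p (ties: chromosome, position, rsid): each
unassigned candidate becomes a lead and absorbs unassigned candidates on
its chromosome within ±1000 kb with r² ≥ 0.1 to the lead.  The p-threshold
is strictly `<`; the 100 kb cis window is inclusive.  r² comes from squared
Pearson correlation of dosages in the derivation cohort (no external LD
panel is assumed).

The score `S_i = Σ_j w_j g_ij` uses the derivation betas as weights, with
dosage alleles aligned (flip `g → 2−g` and the weight's sign when the
file's effect allele is the instrument's other allele; strand complements
resolved by complementing first).  Validation against the censored
biomarker uses proportional-odds logistic regression (statsmodels
`OrderedModel`): category 0 is the below-LOD mass and the detectable range
is split into 4 quantile bins by default — proportional-odds fits are
insensitive to the bin count, which is exposed for sensitivity checks;
bins with fewer than two observations merge downward.

## Estimation

* **One-sample**: logistic (binary) or OLS (continuous) regression of the
  outcome on the standardized score with covariate adjustment.  Reported
  per 1 SD of score.  Logistic fits use Newton MLE (`statsmodels.Logit`).
* **Harmonization**: rsid match, sign flip for swapped alleles, strand
  complement resolution; palindromic (A/T, G/C) variants follow a policy —
  default `frequency_align` with drops inside the (0.42, 0.58) ambiguity
  band; no proxy search (unmatched instruments drop, as the emulated study
  did).
* **Wald ratio** `θ_j = b_Yj/b_Xj` with first-order SE `|σ_Yj/b_Xj|`
  (exposure-side uncertainty ignored — the standard IVW convention; with
  instruments at z ≈ 14 the second-order term is negligible).
* **IVW**: precision-weighted mean with `w_j = b_Xj²/σ_Yj²`, algebraically
  the no-intercept WLS slope of `b_Y` on `b_X`.  The multiplicative
  random-effects variant scales the SE by `max(1, √(Q/(J−1)))`.
* **Cochran's Q** on the Wald ratios, p from χ²(J−1).
* **MR-Egger**: WLS of `b_Y` on `b_X` with intercept, weights `1/σ_Y²`,
  rows oriented so all `b_X ≥ 0`; the intercept estimates average
  directional pleiotropy.  SEs floor the residual variance at 1; p from
  t(J−2).  Egger requires *dispersion* in instrument strength: with
  near-constant `b_X` the slope/intercept split is ill-conditioned, and
  `b_X` measurement error comparable to the `b_X` spread causes regression
  dilution — the recovery tests therefore use a dispersed-strength design.
* **Weighted median**: the value at the 50% point of the weight-ordered
  ratios (linear interpolation of the cumulative weight-percentiles
  `p_j = (Σ_{k≤j} w'_k) − w'_j/2`), SE by a 1000-draw seeded parametric
  bootstrap; consistent while ≥ 50% of weight comes from valid instruments.
* **Sensitivity subsets**: cis-only, pleiotropy-flag exclusion (flags come
  from a user-supplied annotation table), single-lead-per-locus;
  leave-one-out IVW; Bonferroni `min(1, m·p)` with m = 7 for the clinical
  measurement outcomes.

Scaling convention: exposure betas are already per 1 SD of log-exposure, so
ratio estimates are log-ORs per 1 SD of genetically predicted log-exposure;
an `exposure_sd` factor rescales when weights are on another scale.  For
one-sample results the unit is 1 SD of the standardized score, which
coincides with the two-sample unit up to the score-exposure attenuation
√R²; both conventions are carried in each result's `scaling_note`.

## Power

For a score explaining R² of exposure variance in n individuals with case
fraction K, the Wald statistic for a true OR per 1-SD has mean
`√(n·R²·K(1−K))·|log OR|`, giving

    power = Φ( √(n R² K(1−K)) · |log OR| − z_{1−α/2} )

and its inverse for the minimum detectable OR.  With the study's inputs
(n = 337,448; 12,652 cases; R² = 6.3%) this reproduces the published
minimum detectable OR of 1.11 for the nonatherosclerotic composite.  A
per-allele two-sample analogue substitutes `2p(1−p)` for R².  The
approximation ignores logistic non-collapsibility: the marginal score
coefficient is attenuated by the residual exposure variance on the
liability scale, a ~1% effect at OR ≈ 1.3 that grows with the effect size —
empirical power therefore sits a hair below the analytic value (≈ 79% vs
80% at the scaled design below).

**Empirical power** simulates full cohorts at a given true OR, scores
individuals with the generating weights, and counts rejections of the
logistic score test.

## Problem sizes

Calibration checks that need replication use scaled designs chosen to keep
Monte-Carlo error well inside the assertion bands: the type-I/power and
coverage checks run 1,000 replicates at n = 20,000 (case fraction
preserved) or n = 4,000 (coverage), two-sample recovery checks run 1,000
summary-level replicates at the study's instrument scale (J = 34, z ≈ 14),
and single-cohort quantities (variance explained, clumping) use the full
derivation size n = 19,195.  Full-size cohorts (n = 337,448) remain
available through the config and are exercised once in the test suite (case
-fraction calibration).

## Known limitations

* The generator emulates second-moment structure (allele frequencies,
  pairwise LD, variance explained, case fractions, censoring rate), not
  haplotypes, imputation uncertainty, relatedness, or population
  stratification — so passing tests demonstrate estimator correctness and
  calibration under the assumed model, not robustness to those real-data
  features.  The covariate-balance diagnostic will not detect
  stratification the generator cannot produce.
* The ordinal validation model assumes proportional odds; the generator
  satisfies it by construction.
* Wald-ratio SEs ignore exposure-side uncertainty (a second-order effect
  here); weak-instrument settings would need different methods.
* The nonlinear/threshold exposure-outcome hypothesis sometimes raised for
  this biomarker is deliberately out of scope, as are MR-PRESSO,
  mode-based, and multivariable estimators.
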