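# Methods

## Model and estimator chain

The package implements two-sample summary-statistics Mendelian randomization
with a fixed instrument set. Let β_ZX,j be the per-allele effect of SNP j on
the exposure (natural-log 25OHD, from a replication cohort with direct 25OHD
measurements) and β_ZY,j its effect on the outcome (log-odds for binary
outcomes, linear for ln-IgE) from a non-overlapping study. Under the
instrumental-variable assumptions (relevance, no instrument–confounder
association, no pleiotropy), each ratio β_ZY,j / β_ZX,j estimates the causal
effect of a one-unit change in the exposure, and the ratios are pooled by
inverse-variance fixed effects.

Chain, in order:

1. **Unit conversion.** Published ORs and 95% CIs are converted to log-odds
   with SE = (ln U − ln L) / (2z); linear-scale CIs use (U − L) / (2z). The
   z-quantile is the high-precision value 1.959963984540054, not 1.96 — the
   difference is below the reporting precision but avoids a gratuitous
   rounding step.
2. **Harmonization.** Outcome records are aligned to the exposure's effect
   allele; an opposite-allele record has its sign flipped and frequency
   complemented. Palindromic SNPs (A/T, C/G) with both frequencies in
   (0.42, 0.58) are rejected as strand-ambiguous. The packaged tables are
   stored in one orientation with non-palindromic complement alleles (only
   the effect allele was published), so harmonization runs but never flips —
   this orientation assumption is recorded in provenance output.
3. **Wald ratios.** Default SE is the first-order delta approximation
   se_y/|β_ZX|, standard two-sample practice when exposure-side SEs are much
   smaller than outcome-side ones; the second-order form (adding
   β_ZY² se_ZX² / β_ZX⁴) is available by flag. Exposure-side SEs are not
   published and are recovered from the printed F statistics via F = (β/se)²
   when the second-order form is requested.
4. **Pooling and heterogeneity.** Fixed-effects IVW; Cochran's
   Q = Σ w_j (e_j − θ̂)², I² = max(0, (Q − (k−1))/Q), with Q = 0 mapping to
   I² = 0 (not NaN). The I² confidence interval inverts the generalized
   Q(τ²) statistic against χ²(k−1) quantiles (Q-profile) and maps the τ²
   bounds through the Higgins–Thompson "typical" within-study variance
   s² = (k−1)Σw / ((Σw)² − Σw²); bounds are truncated to [0, 1).
5. **Per-SD reporting.** The pooled per-unit estimate is multiplied by −σ to
   give the effect per SD *decrease* of ln-25OHD, with σ = 0.47. σ is the
   one scalar in the chain not identified from the summary tables (the SD of
   ln-25OHD was not published); 0.47 is back-calibrated so the pooled asthma
   OR reproduces the published 1.03, and every report bundle records it in
   provenance. All machine output is unrounded; the human-readable report
   rounds to two decimals (I² to whole percent), matching the source tables.

Sensitivity subsets are named filters over the instruments: leave-one-locus
out (*DHCR7* for population stratification, *CYP2R1*/*CYP24A1* for
pleiotropy) and pathway-restricted sets (synthesis = *DHCR7* + *CYP2R1*,
metabolism = *GC* + *CYP24A1*). The sensitivity report emits N/A exactly for
the subset×outcome cells where no potential bias was flagged (the
CYP2R1+CYP24A1 exclusion applies to asthma only; the CYP2R1 exclusion to
atopic dermatitis and IgE only).

## Instrument validation

F = (β_ZX/se)² measures instrument strength; R² = F/(F + n − 2) and its
inverse are exposed for conversions. The packaged per-SNP F statistics and
variance-explained values are carried verbatim as metadata and never
recomputed from each other: they derive from different adjustment sets and
are mutually inconsistent under any single n, so asserting one against the
other would manufacture a contradiction. The confounder screen applies an
inclusive Bonferroni rule (significant iff p ≤ α/m, α = 0.05, m = 4) —
inclusive because the decision rule is stated as "declared at p ≤ 0.05/4".
LD gating consumes user-supplied pairwise r² from reference panels (default
ceiling 0.01); no genotype-based LD computation is in scope.

## Power

Analytic power uses the normal approximation
NCP = n·R²·b² (variant `plain`) or n·R²·b²·K(1−K) (variant
`case_control_scaled`, K the case fraction), power = Φ(√NCP − z_{1−α/2}) +
Φ(−√NCP − z_{1−α/2}). Both variants exist because published binary-outcome
power statements cannot be uniquely traced to one scaling; `plain` is the
default and reproduces the published anchors (86% for the IgE configuration;
minimal detectable asthma OR ≈ 1.13 vs printed 1.12) with the summed
instrument R² of 0.0036. Those published figures are treated as approximate
anchors (±5 pp / ±0.05 OR), not exact targets, since the exact formula and
R² fed to the original power tool are unstated. The default instrument R² is
the sum of the per-SNP variance-explained column; with n = 15,008 the
childhood-asthma minimal detectable OR computes to ≈1.46 vs a printed 1.33 —
consistent with the published value resting on a larger effective R², and
left as-is rather than tuned. `minimal_detectable_effect` inverts the power
function by bracketed root finding to 1e-10 and round-trips through
`mr_power` to 1e-8.

The Monte-Carlo oracle simulates the model in which the formula is exact: a
standardized instrument score explaining R² of the exposure, and an outcome
whose residual SD *given the score* is one — the unit in which the formula's
b is expressed. (Simulating unit noise around b·x instead inflates the
conditional residual to 1 + b²(1−R²) and deflates power by several points at
b ≈ 0.35; the two parameterizations agree as b → 0.) The test grid uses five
effect sizes at n = 2,000, R² = 0.01, 10,000 replicates, where the analytic
and empirical power agree within 2 percentage points.

## Generative model (synthetic data)

`simulate_cohort` draws, for n individuals: genotypes g_j ~ Binomial(2, f_j)
independently across four loci (defaults: the published allele frequencies
0.62, 0.27, 0.30, 0.19 — loci with all pairwise r² ≤ 0.01 justify
independence; LD is not modelled); a standard-normal confounder C; exposure
x = Σ β_j g_j + γC + ε with ε ~ N(0, 0.47²) and per-allele effects
(−0.052, −0.056, −0.047, −0.027) log-units. With these defaults the total
exposure SD is ≈0.472 — the genetic and confounder contributions are small —
consistent with the calibrated reporting σ. Binary outcomes follow
logit P(Y=1) = α + θ·(x − μ)/σ_x + δC + Σ π_j g_j, where (μ, σ_x) are the
*population* mean and SD implied by the configuration (so θ is "log-odds per
SD of ln-25OHD" exactly, and the intercept solve is deterministic); α is
solved so the population prevalence matches the configured value (default
0.17, the case fraction of the largest outcome sample) to 1e-8, by Brent
root finding on the population-averaged logistic mean computed exactly as a
3⁴-point genotype mixture × 61-node Gauss–Hermite quadrature. Continuous
outcomes use the same linear predictor plus unit-variance noise. π_j ≠ 0
injects pleiotropy (an exclusion-restriction violation); γδ ≠ 0 injects
confounding that biases the naive observational regression by sign(γδ) while
leaving the MR chain approximately unbiased.

`summarize_gwas` turns disjoint index sets into exposure-side OLS and
outcome-side logistic per-SNP summaries, emulating the two-sample design.
The per-SNP logistic fits use an explicit two-parameter Newton–Raphson
(score/information closed forms) because replicated experiments run
thousands of fits; it is cross-checked against statsmodels `Logit` to 1e-6
in the unit tests. Randomness contract: one master seed; per-replicate
generators are spawned from a `numpy.random.SeedSequence`, so experiments
are bit-reproducible and replicates are independent.

What the simulator does *not* emulate: linkage disequilibrium, assortative
mating or canalization (developmental compensation — named as inherently
untestable by this design), ancestry structure, measurement error in 25OHD,
case-control ascertainment (cohorts are population samples with the given
prevalence), or between-study heterogeneity in outcome definitions. Passing
calibration tests therefore demonstrate the estimator chain's correctness
under the assumed causal graph, not robustness to these real-data features.

## Problem sizes in the test suite

Type-I error and coverage: one null cell, n = 20,000, 2,000 replicates
(rejection rate checked against [0.035, 0.065] — approximately ±3 binomial
SDs around 0.05). Parameter recovery: θ ∈ {0.1, 0.2, 0.3}, n = 100,000, 200
replicates, mean within 2 Monte-Carlo SEs; at θ = 0.3 the logistic
non-collapsibility attenuation is ≈1.5% of θ, well inside that band.
Confounding contrast: one cohort of n = 100,000 with γ = −0.3, δ = 0.5.

## Known limitations

- The published per-outcome I² cells (0%, 0%, 15%, 0%) are **not**
  recoverable from the two-decimal published inputs: recomputation from the
  rounded tables gives ≈19–30% for the three binary outcomes. The unrounded
  consortium statistics were never published, so I² correctness is asserted
  through the defining formula (degenerate and two-point cases, bounds), not
  through those cells. Point estimates are insensitive to the rounding
  (±0.02); heterogeneity statistics are not.
- σ = 0.47 is a calibration constant, not a measured quantity; analyses per
  SD of a differently-scaled exposure should override it.
- Only fixed-effects pooling is provided (no MR-Egger, weighted median or
  mode estimators, no random effects): with k = 4 instruments those
  pleiotropy-robust estimators are underpowered to the point of being
  decorative, and sensitivity is handled by locus-exclusion subsets instead.
- Whether the original across-study meta-analysis used inverse-variance or
  sample-size weights is unstated; `ivw_meta_studies` assumes
  inverse-variance.
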