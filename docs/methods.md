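# Methods

## Genotype model and QC

A `GenotypePanel` holds an individuals × variants matrix of effect-allele
dosages in {0, 1, 2} (NaN for missing calls) with 1-based, inclusive
coordinates (VCF/PLINK convention). Variant-level QC retains autosomal
biallelic variants with call rate > 0.99, MAF ≥ 0.05, and exact
Hardy-Weinberg p > 5e-8, evaluated in that order so each removal is
attributed to a single criterion. The HWE test conditions on the allele
counts and sums the probabilities of all heterozygote counts no more
probable than the observed one (ties included) — the standard exact
formulation used by chip-QC toolchains; it is verified against an
integer-arithmetic enumeration oracle in the tests. Person-level QC
(sex concordance, heterozygosity) and imputation are out of scope.

Missing dosages are excluded pairwise for LD and allele frequencies and
mean-imputed (2 × effect-allele frequency) for scoring and PCA, the
PLINK-like default. LD is the squared Pearson correlation of unphased
dosages (composite r²).

Genotype PCs are the left singular vectors (scaled by singular values)
of the mean-imputed, column-standardized dosage matrix, computed after
QC; the sign of each component is fixed by making its largest-magnitude
variant loading positive, so results are bitwise reproducible.

## PRS construction

Clumping is greedy by ascending GWAS p-value (ties: smaller position,
then id): each retained index removes every remaining variant on the
same chromosome within 1,000 kb at r² ≥ 0.1. The *APOE* region
(chr19:44,400,000–46,500,000, GRCh37, bounds inclusive) is excluded
before clumping in the main models; APOE-inclusive models skip the
exclusion and then drop the APOE ε2/ε4 covariates from association
fits. Clumping runs once on the full summary statistics; the threshold
ladder 0.05, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8 (PRS1–PRS7) then
subsets the clumped list, which makes the variant sets nested by
construction. Scores are exact weighted dosage sums (weights on the
summary-stats effect allele, with swapped-allele panels reflected as
2 − G and strand-ambiguous mismatches rejected), then z-scored over the
cohort so association effect sizes are per SD of PRS. A threshold that
retains no variants yields an all-zero score plus a warning record
rather than an error.

## Association scans

Continuous biomarkers are transformed by the rank-based inverse normal
transform with the Blom offset 3/8 (configurable), average ranks for
ties, missing values passed through. The Aβ42/40 ratio is bimodal and
is only analyzed dichotomously; the default calls a ratio strictly
below 0.091 pathologic (the standard direction for CSF; the opposite
strictly-above rule is available behind a flag because published
cutpoints are sometimes printed in the inverted orientation). A ratio
exactly at the cutoff is non-pathologic under either direction.

Linear fits are OLS with intercept (statsmodels), logistic fits are
Newton maximum likelihood with perfect separation reported as an error;
both use complete cases per (model, biomarker) pair with no phenotype
imputation. The covariate set is age, sex, education, MMSE, APOE ε2/ε4
counts (omitted for APOE-inclusive models), and the top 10 genotype
PCs; mediator adjustment appends binary Aβ status. Bonferroni families
are the PRS models tested per biomarker (and stratum). When the scan is
mediator-adjusted, the ratio biomarker is skipped with an explicit
status, since the dichotomized ratio *is* the adjustment variable.
Strata too small for the design (n < predictors + 2) produce
"skipped: insufficient n" rows rather than errors.

## Mediation

The mediation estimator is difference-of-coefficients: c from the
outcome-on-exposure fit, c′ and b with the mediator added, a from a
linear-probability fit of the binary mediator — all presented as
regression coefficients on the same footing, which is what makes
c − c′ and the proportion mediated (c − c′)/c directly comparable
across paths. The product-of-coefficients form is deliberately not
implemented. Uncertainty comes from a nonparametric percentile
bootstrap over individuals (paired rows, default 1,000 resamples,
fixed RNG stream per call) with the fraction-based two-sided p-value
2·min(frac ≤ 0, frac ≥ 0), floored at 1/n_boot. The proportion mediated
is reported as NaN when |c| < 10·SE(c) (guard configurable): a ratio
with a weakly determined denominator is noise, not a percentage.

Two structural properties of this estimator are worth knowing when
interpreting synthetic checks. First, with a composite exposure that
carries both mediator-path and direct-path variants, the mediator acts
as a proxy for the mediator-path component even when its own causal
effect on the outcome is zero, so the indirect estimate need not center
on zero in that design; the null-b-path validation therefore uses an
architecture whose exposure acts only through the mediator. Second,
the proportion mediated is monotone in the planted mediator→outcome
effect, which the tests verify on a three-point grid.

## Decomposition heuristic

Step 1 (leave-one-out): for each of the n variants, the PRS is rebuilt
from the other n − 1 (same weights), standardized, and regressed
(linear-probability, standard covariates) on the mediator; the record
keeps the p-value and whether removal strengthened (p_loo < p_full) or
weakened the association. The strengthened/weakened split is reported
but not used as a filter — ranking proceeds over all records. Step 2:
variants are ordered by leave-one-out p (ascending by default: the
variants most dispensable for the amyloid path first; ties broken by
id), and for every k the top-k PRS (re-standardized per k) is fitted
against the outcome with and without mediator adjustment plus a
screening bootstrap mediation. Candidate mediator-independent models
have mediation p ≥ α and outcome association p < α both adjusted and
unadjusted; the optimal subset minimizes |β_adj − β_unadj| (ties to the
larger k). The exclusive mediator-dependent subset is the complement of
the **union of all** candidate subsets — variants in no
mediator-independent model — not merely of the optimal one. Both final
subsets are re-validated at the full bootstrap count and entered
jointly in a two-score model. The screening bootstrap count is reduced
(default 200) because the profile runs one mediation per k; the final
validations use 1,000. The whole decomposition is a pure function of
(data, parameters, seed). With no planted effects anywhere the outcome
association itself fails the screen, so the candidate list is empty —
an explicitly valid outcome.

## Synthetic cohort

The generator is the testbed's ground truth, with defaults fixed once:

* **Genotypes** — biallelic, MAF ~ Uniform(0.05, 0.5), HWE by
  construction: each haplotype thresholds a latent Gaussian AR(1)
  process (lag-one correlation `ld_rho` within blocks, independent
  across blocks) at the MAF quantile. This gives tunable pairwise r²
  decay, which is all clumping needs; it does not emulate real human
  LD maps, admixture, or imputation dosages. Blocks are spaced 2 Mb
  apart so clumping windows never straddle them. Optional missingness
  is completely at random (default 0).
* **Summary stats** — causal variants carry their standardized effect
  converted to the per-allele scale; estimates add Gaussian noise with
  SE = 1/√(2·N·p(1−p)) for GWAS size N (default 50,000), p-values from
  the two-sided normal z. N = ∞ is the noise-free limit.
* **Phenotypes** — mediator = indicator(liability > empirical
  (1−prevalence)-quantile), liability = Σ w_dep·z(G) + covariates +
  N(0,1); P-tau outcome = b_med·mediator + Σ w_ind·z(G) + covariates +
  N(0,1), mapped to a positive concentration scale by a strictly
  monotone transform (irrelevant after INT); T-tau adds independent
  noise to the same signal; NfL and Aβ1-38/1-40 are null biomarkers;
  Aβ1-42 is built from a bimodal ratio so that dichotomizing at the
  cutoff reproduces the mediator exactly. Defaults: prevalence 0.4,
  w_dep 0.25, w_ind 0.15, b_med 0.8 — a strong-effect regime (per-SD
  effects ≥ 0.15) in which recovery is expected, chosen once and not
  tuned per test. Covariates are placeholders (age ~ U(60, 85), sex ~
  Bernoulli(0.5), education ~ U(6, 20), MMSE 24–30, APOE counts
  multinomial), not estimates of any real cohort.

Because the panel is a single homogeneous population, genotype PCs
estimated from a ~100-variant panel are noise directions that overlap
the very score under test, and conditioning on them induces a spurious
PRS–mediator correlation (a small-panel artifact; real PC covariates
come from genome-wide data where this overlap is negligible). The
pipeline keeps PCs in the scan covariates, but the mediation and
decomposition recovery analyses adjust for the demographic covariates
only. Passing recovery tests therefore demonstrates the estimators'
correctness under the planted architecture, not robustness to
population stratification.

## Problem sizes and numerical choices

Recovery analyses use n = 5,000 individuals with 100 variants
(10 dependent / 20 independent / 70 null) and screening bootstraps of
200; calibration uses 1,000 phenotype replicates at n = 500 and 100
mediation runs at 1,000 resamples — sizes at which every Monte-Carlo
bound tested has comfortable margin while the whole suite runs in
minutes on one core. Oracle equivalence is asserted at 1e-12 (scores,
HWE vs enumeration), 1e-10 (OLS vs normal equations), and exact set
equality (clumping vs an independent greedy restatement). Bootstrap
seeds split deterministically from one root via `SeedSequence`; reruns
are byte-identical, which the pipeline manifest checks by SHA-256.

## Known limitations

Single-population genotypes only; no strand-flip reconciliation against
a reference; no LDpred-style shrinkage scores; no exposure–mediator
interactions or multiple mediators; mediation is associational (no
sensitivity analysis for unmeasured confounding); gene-set enrichment
of the identified subsets is out of scope.
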