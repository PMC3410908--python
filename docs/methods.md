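# Methods

This note records the statistical model behind each stage of the package,
the defaults and why they were chosen, the numerical choices that affect
results, and what the synthetic-data tests do and do not demonstrate.

## Synthetic cohorts

Genotypes are simulated per SNP as two independent Bernoulli(MAF) alleles,
so each column satisfies Hardy–Weinberg equilibrium by construction. A SNP
declared in LD with a partner is drawn jointly from the two-locus haplotype
distribution whose joint minor-haplotype frequency is
`p1*p2 + r*sqrt(p1 q1 p2 q2)`; the Fréchet bounds on that frequency define
attainability of the requested allelic correlation `r`, and unattainable
requests are rejected rather than clipped.

Disease status follows a logistic model: logit P(D) = intercept +
Σ marginal log-OR × dosage + Σ interaction terms, where the interaction
coding is the dosage product (additive×additive), carrier-indicator product
(dominant×dominant), double-homozygote-indicator product
(recessive×recessive), or a free 3×3 table of log-odds offsets. Cohorts are
ascertained retrospectively: a large source population is simulated and
rejection-sampled to exact case and control quotas, mirroring case-control
recruitment. Under a rare disease the genotype–disease odds ratios of the
source model are preserved in the ascertained sample; the default intercept
corresponds to ~1% prevalence. An intercept implying prevalence below 1e-6
is rejected up front because rejection sampling cannot reach the case quota.

Defaults mirror a discovery cohort of 2,967 cases and 3,075 controls.
Covariates, age/sex matching structure, population stratification,
genotyping error and imputation uncertainty are deliberately *not*
simulated: the tests implemented here contrast genotype frequencies only,
so calibration results on these cohorts say nothing about confounding
robustness on real data. Missingness is off by default; a uniform missing
rate is available because real PED files contain it.

## Marginal screen, pruning and tiers

The single-SNP screen is the 1-df allelic trend test implemented as the
closed-form logistic score test on dosage (equivalent to Cochran–Armitage),
chosen over an MLE-based LRT because it is immune to separation on extreme
tables. Monomorphic SNPs get no p-value and never enter tiers.

LD pruning is greedy in ascending marginal-p order (ties broken by SNP id):
a SNP is kept iff its dosage-correlation r² with every previously kept SNP
— and with the keep-list of earlier analysis tiers — is below 0.5.
Smaller-p retention preserves signal; the composite (genotypic) r² is used
because phase is unknown (the haplotype-EM r² agrees with it under HWE and
is available as a cross-check).

Tiers: Analysis 1 = annotated risk-factor SNPs; Analysis 2 = (marginal
p ≤ 1e-3 set minus Analysis-1 SNPs and their r² ≥ 0.5 proxies) × Analysis-1
set; Analysis 3a = within the same marginal set; Analysis 3b = within the
p ≤ 1e-2 set, dropping pairs whose members (or their LD proxies) were
co-tested earlier. The proxy-level pair-dedup rule is what makes the tier
arithmetic consistent: pairs among proxies of earlier-tier SNPs count as
already tested even though the proxies themselves were pruned.

## The pairwise tests

**Genotypic LRT.** Case status is regressed on two indicator columns per
locus (reference: homozygous major) with and without the four
product-indicator columns, on counts aggregated to the ≤9 observed
compound-genotype cells (statsmodels binomial GLM/IRLS). Degrees of freedom
are the rank difference of the two designs restricted to observed cells —
equivalent to dropping non-identified interaction columns, and also correct
when a main-effect cell such as (0,0) is empty. With df so defined the full
model is saturated on the observed cells, so the LRT equals the deviance of
the main-effects fit; this identity is verified against an independent
direct-likelihood oracle to 1e-6. Non-convergent fits are flagged
infeasible rather than reported.

**Allelic contrast.** Each group's 3×3 table is collapsed to allele
combinations: n11 = 4n(0,0)+2n(0,1)+2n(1,0)+n(1,1) and symmetrically, the
double heterozygote contributing one count to each cell. The statistic is
z = (ln OR_case − ln OR_control) / sqrt(Σ 1/cell) over the 8 cells, two-
sided normal p. Feasibility requires all 8 cells positive — the zero-cell
rule was chosen over a minimum-count rule; the infeasible fraction in any
given screen is data-dependent. Within-subject dependence of the four
allele pairs is ignored by the variance formula; under HWE and locus
independence the null z is standard normal empirically (simulated sd 0.98),
matching the test's intended operating regime.

**Case-only.** z = ln OR_case / sqrt(Σ 1/cell over case cells). Valid as an
interaction test only when the loci are independent in the source
population; the test suite demonstrates the classical failure mode (LD
between loci inflates rejections) as an anti-example.

**1-df constrained tests** add the coded product to a logistic model whose
main effects use the same coding (dosage for additive, indicators for
dominant/recessive), and report the Wald log-OR and SE used downstream by
the meta-analysis. Missing genotypes are handled by pairwise-complete
deletion throughout; all p-values are two-sided.

## Permutation null and significance threshold

Each permutation shuffles phenotype labels once globally and re-runs the
whole battery, preserving inter-SNP correlation; the minimum feasible p is
recorded (a permutation with no feasible test records 1 with a warning).
The battery minimum is fitted with a maximum-likelihood Beta(a, b) on
(0, 1) from a method-of-moments start (minimum 30 permutations). The
family-wise threshold is the 0.05 quantile of the fitted beta — the point t
with P(min p ≤ t | H0) = 0.05. On independent batteries this reproduces the
closed form 1 − 0.95^(1/m) and sits within a few percent of Bonferroni
0.05/m; realised family-wise error is nominal in repeated experiments. The
threshold estimated from only 200 permutations has ~19% typical relative
scatter around the 10,000-permutation value, so its rapid stabilisation is
a typical-case property, and the convergence check asserts the median over
independent streams. QQ expectations use the per-rank mean of order
statistics across permutations with a 2.5/97.5-percentile envelope; ragged
batteries (differing feasibility) are aligned on the common length with a
warning.

## Power surfaces

Power is expressed as the minimum interaction OR detectable at a target
probability (default 80%). The analytic route builds the expected
case/control × 9 table under the two-locus logistic model with **zero
marginal effects** (the conventional interaction-only alternative) and the
candidate OR, conditions expected counts on the case and control totals
(retrospective ascertainment), and uses:

- genotypic / 1-df LRT: the deviance of the null fit to the expected table
  as the noncentrality of a noncentral chi-square at the test's df;
- allelic: the expected z as the mean shift of a unit normal.

Control genotype frequencies default to the rare-disease limit (controls
mirror the source population); a finite prevalence can be supplied. The
detectable OR is found by bisection with an expanding bracket from OR = 1
(which keeps the expected table inside the regime where the IRLS null fit
is well conditioned), to power tolerance 1e-3, reported to 2 decimals;
targets unreachable at OR = 20 are reported as infinite. Alphas below 1e-30
are rejected as outside the normal/chi-square approximation. The analytic
route is cross-checked against a simulation oracle (repeated cohort draws
through the actual test implementations) within Monte-Carlo error, and the
50%-vs-80% power comparison is made on the log-OR scale, on which the
noncentrality scales.

At a full-scale design (2,967/3,075, additive×additive, no marginal
effects) the analytic surface gives detectable ORs of 1.60 (MAF 0.2) and
1.40 (MAF 0.5) at α = 1.51e-6 for the genotypic test, and a ~13.7%
reduction in detectable log-OR when the power target drops from 80% to
50% — numbers recomputed live by `scripts/acceptance.py` and the acceptance
tests, not stored.

## Haplotype × SNP interaction (simplified framework)

Two-SNP haplotype frequencies come from the standard EM for unphased
genotypes (only the double heterozygote is ambiguous), iterated to 1e-8
frequency convergence with a 500-iteration cap and a monotone
log-likelihood. Interaction with a third SNP is tested by substituting the
posterior-expected dosage of the target haplotype into the 1-df additive
interaction LRT. This expected-dosage substitution is a stated
simplification: it ignores phase-uncertainty variance, is exact whenever
phase is unambiguous (where it reduces to the SNP×SNP test), and slightly
understates uncertainty otherwise. Multi-SNP haplotypes and reference-panel
phasing are out of scope.

## Validation and meta-analysis

Discovery pairs with interaction p within three orders of magnitude of the
analysis threshold are carried forward; validation applies a Bonferroni
per-pair level 0.05/n. The meta-analysis combines per-study 1-df additive
interaction log-ORs by inverse-variance weighting (heterogeneity Q is
reported, not tested), even when discovery used the 4-df genotypic test —
combining the 4-df statistic would require the full coefficient vector and
its covariance across studies, which the results schema does not carry;
the choice is noted in output metadata.

## Problem sizes used by the test suite

Simulation-backed checks run at desk scale chosen for tight Monte-Carlo
envelopes at interactive runtimes: type-I calibration at 2,000 replicates
of 1,500+1,500 subjects; coefficient recovery at 200 replicates of
3,000+3,000; family-wise error at 500 mini-experiments of 300 permutations
× 100 tests; empirical-vs-analytic power at 600 replicates. Pair-count
arithmetic is exact at the published set sizes (242/643/6,066-scale
enumeration is pure combinatorics). The full suite completes in about a
minute on one CPU.

## Known limitations

- Calibration and power results are proven on HWE cohorts without
  covariates or stratification; real-data deviations (batch effects,
  cryptic relatedness, differential missingness) are untested here.
- The allelic test's variance formula ignores within-subject allele-pair
  dependence; it is calibrated under HWE + locus independence but is not a
  general-purpose replacement for the genotypic LRT.
- Power assumes the causal pair is typed; attenuation through incomplete
  LD between causal and typed variants is not modelled.
- The case-only test is provided with its independence caveat and a
  demonstrated failure mode, not as a default.
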