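# Methods

## Scope and model

The package implements a case-control analysis chain for small SNP panels:
SNP-level quality control, a covariate-adjusted logistic association
screen, D′-based linkage-disequilibrium pruning, a generalized
multifactor dimensionality reduction (GMDR) search for SNP–SNP
interactions, an integer risk-allele polygenic risk score (PRS) over the
selected model, and lifestyle-stratified adjusted odds ratios with
interaction tests. A synthetic-cohort generator supplies data with the
statistical structure each stage assumes, so the chain is testable without
restricted cohort genotypes.

Throughout, the outcome model is logistic: a binary disease indicator
with log-odds linear in the analysis terms. All odds ratios are Wald
estimates `exp(β)` with 95% CIs `exp(β ± 1.96·SE)`; nested-model
comparisons use likelihood-ratio chi-square tests.

## Synthetic cohort generator

**Genotypes.** Each SNP is drawn under Hardy–Weinberg equilibrium by
sampling two Bernoulli(MAF) haplotypes per individual. A SNP may instead
be coupled to a previously declared partner through the two-locus
haplotype distribution implied by (MAF\_a, MAF\_b, D′): the minor alleles
co-occur with frequency `p_a·p_b + D`, `D = D′·min(p_a(1−p_b), (1−p_a)p_b)`.
Only positive coupling is generated (the pruning stage consumes |D′|, so
sign is immaterial). Missing calls are injected completely at random at a
per-SNP configurable rate (default 0: realized post-QC missingness in chip
data of this kind is not published, so the neutral default is none).

**Exposures and covariates.** One vectorised draw per variable in config
order. Defaults emulate a middle-aged Korean health-examinee population:
age ~ N(53.5, 8²) truncated at 40 y, male fraction 0.35,
BMI ~ N(24.0, 2.9²) kg/m², WBC ~ N(5.7, 1.55²) ×10⁹/L, energy intake as
percent of estimated need ~ N(98.7, 31.5²), macronutrient energy fractions
near 71.5/13.5/14.0 En% (carbohydrate/protein/fat), smoking 73.1/15.6/11.3%
never/former/current, coffee a zero-inflated gamma in g/day with roughly a
third of subjects under the 3 g/day cut, and 38 dietary-component intakes
as gamma(4, mean/4) variables around typical adult daily means. These are
population-scale summaries, not individual-level survey joint
distributions: covariates are drawn independently, so real-world
correlations (age–smoking, energy–macronutrients) are absent unless
explicitly planted through the effect model.

**Outcome.** One Bernoulli draw per sample from
`expit(intercept + Σ additive + Σ epistasis-cell + Σ covariate + Σ G×E)`.
Epistasis is planted as a 3×3 table of log-odds offsets indexed by the
dosage pair — not as penetrance probabilities — so additive and epistatic
parts compose inside a single logistic predictor, matching the downstream
analysis. The `checkerboard_epistasis` helper builds a parity-patterned
table whose joint effect has only weak marginal projections. A
`TruthRecord` stores the planted pairs, implied risk alleles, and the
master seed.

**Reproducibility.** Each public generator takes one integer seed;
`simulate_cohort` derives three independent sub-stream seeds (genotypes,
exposures, outcome) via a seed sequence. Identical (config, seed) yields
bit-identical cohorts, including injected missingness.
`simulate_case_control` accumulates population batches until fixed
case/control quotas are met; the default template for rare-outcome
realism is ~0.6% prevalence, while power-oriented tests use balanced
designs.

## Quality control

Per SNP: call rate, minor allele frequency folded onto the rarer allele,
heterozygote fraction, and a two-sided exact Hardy–Weinberg test. The HWE
p-value sums the probabilities of all heterozygote counts (conditional on
the allele counts) no more likely than the observed one; the conditional
distribution is evaluated with a recurrence anchored at its mode for
numerical stability, and matches direct multinomial enumeration exactly
(tested exhaustively for all tables with n ≤ 50).

Exclusion thresholds: missing rate < 4%, MAF > 0.01, HWE p > 0.05. Chip
genotyping accuracy (an intensity-level criterion) is approximated by call
rate, the only proxy available from genotype matrices. The 30%
heterozygosity ceiling is applied **per sample**, not per SNP: under HWE a
MAF-0.3 SNP has ~42% heterozygotes, so a per-SNP 30% cap would remove
every common SNP; excess sample-wide heterozygosity (a contamination
signal) is the standard meaning. High-het samples are listed in the QC
report and excluded only on request (`filter_samples=True`), since sample
QC normally precedes SNP QC.

**LD.** D′ between unphased SNP pairs uses EM haplotype-frequency
estimation (double-heterozygote ambiguity split between cis and trans
resolutions proportionally to current frequency products; convergence
tolerance 1e-8). Pruning is greedy: while any retained pair has
D′ ≥ 0.4, drop the member with the larger association p (ties: the later
SNP in genomic order). The threshold statement is read as *removing*
strongly linked pairs, i.e. retained panels have all pairwise D′ < 0.4.

## Association engine

Logistic fits are Newton/IRLS maximum likelihood (tolerance 1e-10, ≤100
iterations) via statsmodels, wrapped with rank and completeness checks;
quasi-complete separation is returned as a flagged non-converged fit
(|coefficient| ≥ 30 or non-finite SEs), never as silent output. The GWAS
scan codes genotypes additively (0/1/2 minor-allele dosage — the standard
convention, and consistent with risk-allele counting downstream), restricts
to complete cases per SNP, and flags SNPs at the screening threshold
α = 5·10⁻⁴ with no genomic-control correction. Two named covariate presets
are exposed (`covariate_set_1` for the screen, `covariate_set_2` adding
activity/smoking/alcohol) rather than guessing a single set; categorical
covariates enter as reference-coded indicators.

## GMDR engine

Score residuals `s_i = y_i − p̂_i` come from the covariates-only logistic
fit (intercept-only if no covariates), so they sum to zero. For a k-SNP
combination, samples with complete genotypes are pooled into 3^k cells; a
cell is high-risk iff its residual sum exceeds the threshold T = 0 — the
natural convention for residuals centred at zero; empty or unseen cells
default to low-risk (no training evidence of elevated risk).

Cross-validation is stratified by case status (at sub-percent prevalence,
unstratified folds would regularly contain no cases) with seeded
round-robin assignment; class fold sizes differ by at most one. Per fold,
cells are labelled on the 9/10 training part; TRBA is the training
balanced accuracy and TEBA the held-out balanced accuracy, with test cells
unseen in training predicted low-risk. Folds whose training or test part
is single-class are recorded as skipped.

The exhaustive search evaluates every k-combination for each k in range
(guarded by an explicit combination budget). Fold-best is the combination
with the highest TRBA in that fold (ties by lexicographically smallest
SNP-id tuple, making results independent of enumeration order). The per-k
best model is the modal fold-best; its CVC is the number of folds it wins
(ties broken by higher mean TEBA, then lexicographic ids). The overall
best across k minimises the TEBA signed-rank p (ties: higher CVC, then
higher TEBA). Both TEBA and TRBA signed-rank p-values are reported;
selection uses TEBA's, the held-out quantity.

**Signed-rank test.** Exact two-sided Wilcoxon signed-rank against the
null accuracy 0.5: zero differences are dropped with a warning, tied
magnitudes get midranks, and for up to 20 informative folds the full 2^n
sign-pattern distribution is enumerated (exact even under ties); beyond
that, the normal approximation applies. With ten all-positive distinct
folds the minimal p is 2/2¹⁰ ≈ 0.00195.

## PRS and stratified analysis

Risk alleles are assigned from the adjusted per-allele OR (minor allele if
OR > 1, major if OR < 1; OR exactly 1 is an error rather than an arbitrary
choice). The PRS is the integer risk-allele count summed over the model's
SNPs. Samples missing any mapped genotype are excluded and flagged by
default — imputation would break integer score semantics — with
expected-dosage imputation available behind a flag. Categories come from
fixed cut points (the eight-SNP replication preset `gc8` pins 0–6 / 7–8 /
≥9) or empirical tertiles with ties assigned to the lower category.

Stratum-specific ORs fit one logistic model per stratum level (so each
level's low-PRS group is its own reference); a pooled-reference variant is
available behind a flag since either reading of "the low-PRS group" is
defensible. Inestimable cells (empty, single-class, separated) are
flagged, never filled in. The PRS × stratum interaction is tested by
logistic likelihood-ratio test on the product terms with
(categories−1)×(levels−1) degrees of freedom — for a binary outcome this
is the likelihood-based analogue of a two-way ANOVA interaction on
incidence, and it shares machinery with the OR fits; an ANOVA-style
cell-incidence table is emitted alongside for comparability with
incidence bar charts. Stratifiers follow the conventional cut points
(WBC < 4×10⁹/L, coffee < 3 g/day, energy < estimated need,
carbohydrate < 65 En%, protein < 13 En%, fat < 20 En%, never-smokers vs
former+current), all strict `<` at the boundary.

The simplified dietary inflammatory index is
`DII = Σ_c score_c · intake_c / 100` over 38 components. The shipped score
table follows the widely used literature-derived convention
(positive = pro-inflammatory); calibrated analyses should supply their own
table — the defaults exist so the arithmetic and its linearity are
testable.

## Numerical choices

- HWE recurrence anchored at the modal heterozygote count (overflow-free
  up to cohort scale); observed-probability comparisons use a 1e-12
  relative tolerance.
- EM for haplotype frequencies: tolerance 1e-8, ≤1000 iterations; D′
  clipped to [0, 1].
- IRLS: relative tolerance 1e-10, ≤100 iterations; separation guard at
  |β| ≥ 30.
- GMDR fold-best TRBA comparisons use a 1e-12 tolerance before falling to
  the lexicographic tie-break.
- LRT rejects "full worse than reduced" beyond −1e-8 as a nesting
  violation.

## Problem sizes

Tests and the reproduction script run at deliberately modest scale: the
planted-interaction power check uses 2,000 cases / 2,000 controls over ten
SNPs with a 3.5-fold per-cell odds contrast (the pair search is then
essentially deterministic — CVC 10/10 across seeds); calibration checks
use 100–200 replicates at n = 600–5,000; parameter recovery uses
n = 20,000 for a single additive OR. A full cohort-scale run (tens of
thousands of samples, hundreds of screened SNPs, k up to 8) uses the same
code paths; only the combination budget and runtime grow.

## Known limitations

- **Significance of a searched model is anti-conservative.** The
  signed-rank test on fold TEBAs is miscalibrated for the search winner,
  for two reasons that do not vanish with sample size: the winner's curse
  (best-of-45 selection inflates the selected pair's TEBA to ~0.53 under
  the null) and fold dependence (the ten fold TEBAs share 9/10 of their
  training data, so even a prespecified pair exceeds the 5% nominal level
  in ~23% of null runs). Model *selection* (CVC, TEBA ranking) is
  unaffected; calibrated p-values for a searched model would require
  permutation, which is out of scope. Reported signed-rank p-values should
  be read as descriptive.
- The generator draws covariates independently and simulates no population
  stratification, relatedness, haplotype phase output, or genotyping-batch
  structure; passing tests demonstrate correctness of the statistical
  machinery under the stated generative model, not robustness to those
  real-data features.
- The DII score table is a testing default, not a calibrated instrument.
- LD simulation couples minor alleles positively only; negative-D
  haplotype structure is not generated (pruning consumes |D′| and is
  unaffected).
- At realistic (~0.6%) prevalence, stratified OR cells can be empty or
  separated; such cells are flagged inestimable by design rather than
  estimated by penalisation.
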