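# Methods

## Scope and model

`prsurv` implements a germline-pharmacogenomics analysis chain for
immune-related adverse events (irAE): fine-map a case-control GWAS from
summary statistics and a linkage-disequilibrium (LD) reference, build a
polygenic risk score (PRS) from the fine-mapped signals, test the score
against time-to-irAE and overall-survival (OS) outcomes in a multi-arm
trial cohort, identify the driver variants with a non-negative survival
lasso, and evaluate the score as a pre-treatment predictor. Every stage is
exercised end to end on synthetic data whose generators are first-class,
tested code.

## Fine-mapping

Loci are ±500 kb windows around genome-wide-significant lead variants
(p < 5×10⁻⁸), merged to a fixpoint per chromosome. Within a locus,
conditionally independent signals come from forward selection on
approximate conditional statistics computed from summary z-scores and the
LD matrix R:

    z_{i|S} = (z_i − R_{iS} R_{SS}⁻¹ z_S) / √(1 − R_{iS} R_{SS}⁻¹ R_{Si})

This identity is exact for standardized genotypes at a common sample size;
we use it in place of full allele-frequency/effective-n weighting because
the approximation is validated directly against joint logistic regression
on individual-level data (correlation of conditional z-scores 0.9999 at
n = 8000 in the acceptance suite). Conditional β is z_{i|S}·σ_i with σ
kept at its marginal value. Candidates with |r| > 0.9 to any selected SNP
are masked from conditional testing (collinearity guard, configurable);
a conditional-variance term below 1e−8 also masks a variant. Selection
stops when the best conditional p ≥ 5×10⁻⁸.

For each selected SNP the others are conditioned out and per-variant
approximate Bayes factors are computed from the conditional β and σ:

    r = W/(W+σ²),  z = β/σ,  ABF_H0 = exp(−z²r/2)/√(1−r),  ABF = 1/ABF_H0

with prior variance W = 0.04 on the log odds ratio (the 97.5% point of
the implied prior on the odds ratio is 1.48). Posterior probabilities of
association (PPA) normalise the ABFs over the locus's unmasked variants,
and the 99% credible set is the minimal descending-PPA prefix whose
cumulative PPA reaches 0.99. Ties in PPA (and in lead selection) break by
smaller position, then lexicographic allele order, making the output
invariant to input ordering.

Gene annotation of a credible-set span reports TSS inside the span
plainly, appends the two closest TSS within 500 kb of the span ends as
`NAME(kb)` (distance rounded to integer kb), and collapses to `-` when
more than 3 TSS fall inside the span.

## Score construction and scoring

One entry per independent signal: the max-PPA variant with its
conditional effect size as weight (Ŝ = Σ β_i·G_i over risk-allele
dosages). Missing dosages are imputed as twice the effect-allele
frequency. Raw scores are quantile-normalised to the standard normal with
Φ⁻¹((rank − 0.5)/n) and average ranks for ties; the (rank − 0.5)/n offset
is fixed for all n for determinism. Normalisation is computed once over
the combined trial cohort (all arms) before any arm-level analysis, so
"per unit PRS" always means per SD of the pooled score distribution.

## Quality control

The WGS-cohort rulebook, in order: genotype calls with GQ ≤ 20 are set
missing; variants with call missing rate > 0.1 are removed, then samples
with within-sample missing rate > 0.1; heterozygous allele balance
(summed AD over het calls per variant) must lie in [0.3, 0.7] with an
exact two-sided binomial p ≥ 5×10⁻⁸ against 0.5 (minimum-likelihood
two-sided convention); a Hardy-Weinberg exact test conditioning on allele
counts at p ≥ 5×10⁻⁸; per-sample inbreeding F = 1 − observed/expected
heterozygosity (expectation from within-cohort frequencies) within 5 SD
of the mean; and five rounds of PCA outlier removal at 6 SD on the top 10
eigenvectors, with a final PCA retaining 5 eigenvectors. Supervised
ancestry and relatedness pruning are represented by a pass-through stage
that accepts precomputed labels, keeping the pipeline position without
re-deriving published tools. The LD-panel filter keeps variants by a
tiered INFO/MAF rule (INFO > 0.3 / 0.6 / 0.8 / 0.9 as MAF falls through
0.03 / 0.01 / 0.005 / 0.001; MAF < 0.001 always removed); tier bounds are
treated as lower-exclusive/upper-inclusive since the printed ranges do
not specify inclusivity.

Harmonization matches external statistics to the panel by (chrom, pos),
orients the effect allele to the panel's dosage-counted (alt) allele
(a swapped match flips β and complements the frequency), removes
strand-ambiguous A/T and C/G variants, and excludes the MHC interval
chr6:28,510,120–33,480,577 with inclusive ends.

## Survival machinery

The Cox engine maximises the stratified partial likelihood over counting-
process intervals (tstart, tstop] by Newton-Raphson with step-halving,
converging at |Δ log-lik| < 1e−8 within 50 iterations; Efron tie handling
is the default with a Breslow flag. It is written in-package because the
penalized solver reuses the same partial-likelihood derivatives; fits are
cross-checked against lifelines in the tests. 95% CIs use exp(β ± 1.96·SE).

The irAE→OS analysis uses a time-dependent covariate that is 0 before
irAE onset and 1 after, removing immortal-time bias; an onset at or past
the end of follow-up leaves the patient unexposed throughout. The
meta-analysis reports two estimators: the primary stratified fixed-effect
Cox (one baseline hazard per arm, genotype eigenvectors as fixed
covariates) and DerSimonian-Laird random-effects pooling of per-arm
univariable log-HRs as the heterogeneity-aware alternative; the
random-slope mixed Cox of specialised tooling is intentionally replaced
by this pair of standard, testable estimators. Arms without events drop
from the pooling but remain in the stratified fit.

Landmark analysis conditions on survival to day 150 ("first 5 months";
the day count is our fixed convention, configurable) and classifies
exposure by irAE occurrence within the window. Kaplan-Meier curves carry
Greenwood-based 95% bands and median survival via lifelines; cumulative
incidence is reported as 1 − KM (death is not treated as a competing
risk; a Fine-Gray treatment is out of scope and would shrink the
incidence estimates somewhat).

Thyroid events derive from longitudinal TSH series: hypothyroid onset is
the first measurement strictly above 5 mU/L; hyperthyroid onset the first
below 0.4 mU/L (suppressed TSH — the lower bound is this package's
convention, as only the hypothyroid threshold is externally fixed);
a symptomatic event is concordant iff an abnormal measurement exists in
the closed window [event − 7 d, event].

## Survival lasso

The design matrix entry for patient i and score variant p is the
risk-allele dosage times the conditional effect size; negative weights
are re-oriented to the risk allele so penalized entries are non-negative.
Eigenvector columns are appended unpenalized and unconstrained. The
solver is cyclic coordinate descent inside an IRLS approximation of the
Breslow partial likelihood: the score vector u = ∂ℓ/∂η is exact and the
working weights use the exact diagonal curvature e^η Λ − e^{2η} Ψ floored
at 1e−5, so the fixed point satisfies the exact KKT conditions (verified
to 1e−5 in the tests: active coordinates have gradient equal to λ, zero
coordinates have gradient ≤ λ). Variant coordinates are projected onto
[0, ∞) by the thresholded update max(0, (g − λ)/h). Convergence is
declared at a maximum coefficient change below 1e−7 or a relative
log-likelihood plateau below 1e−9; cross-validation path fits use a
looser 3e−4 tolerance with warm starts, since deviance curves are
insensitive at that scale.

The penalty grid has 100 log-spaced values from λ_max (the smallest λ
zeroing every penalized coefficient, computed from the score at the null
model after fitting the unpenalized columns, inflated by 0.1% so the top
grid point reproduces the null exactly) down to 10⁻³·λ_max. Out-of-fold
deviance uses the Verweij-van Houwelingen estimator (−2 times full-data
minus training-fold partial likelihood), the standard choice for Cox
cross-validation and far more stable than a raw test-fold likelihood when
folds carry few events. Folds are stratified by event status (an
all-censored fold is re-drawn, bounded retries); each repeat picks the
grid λ minimising mean out-of-fold deviance ("best" = minimum, not the
1-SE rule) and the returned λ* is the geometric mean of per-repeat picks
(averaging on the log scale, the penalty's natural scale). Importances
multiply non-zero coefficients by the conditional effect sizes and
normalise absolute values to sum to one.

The control-arm null check applies the λ* estimated on the treated
cohort to the control-arm design. The minimum-deviance rule without the
1-SE margin can sit one grid notch below λ_max on pure noise and admit a
couple of tiny coefficients when the control CV is run stand-alone, so
the matched-penalty comparison is the form we test and report.

## Predictor evaluation

PPV/sensitivity curves use the closed predicted-positive rule
(score ≥ threshold); thresholds with no predicted positives carry an
explicit undefined marker (NaN), not 0 or 1. The cross-validated effect
size is the per-test-fold |mean(cases) − mean(controls)| / SD(fold
scores), averaged over 4 stratified folds. Because of the absolute value,
its null expectation is the half-normal mean √(2/π)·SE(diff), not zero;
the tests assert that analytic floor. Analytic power uses the two-sample
normal approximation Φ(d/s − z_{1−α/2}) + Φ(−d/s − z_{1−α/2}),
s = √(1/n₁+1/n₂), cross-checked against Monte Carlo to 0.01. The
composite-subgroup hazard ratio contrasts all-high (female, above-median
PRS and baseline TSH) against all-low patients, with medians taken over
the full supplied cohort.

## Synthetic data: what it emulates, and what it does not

Haplotypes use a first-order copying process within LD blocks: variant j
copies variant j−1 with probability ρ, else draws a fresh allele at a
rate solved so the marginal frequency stays on target; each block draws
one base frequency from its configured range with ±0.02 per-variant
jitter. Adjacent-variant correlation is ρ with geometric decay, and
blocks are independent. This captures the block/decay structure that
conditional analysis and credible sets rely on, but not recombination
hotspots, allele-frequency-dependent LD, imputation error, or
non-European LD — so passing tests demonstrate algorithmic correctness
under idealised LD, not robustness to reference-panel mismatch.

Case-control cohorts quota-sample from a logistic liability model with a
sparse architecture (default: three loci, one carrying two independent
signals, per-allele log odds ratios ≈ 0.4, population prevalence 5%);
the intercept is solved by root-finding on a Monte-Carlo batch of linear
predictors. Quota sampling mirrors GWAS ascertainment rather than
population sampling.

The trial generator draws per-arm exponential (optionally Weibull)
event times with hazard h₀(arm)·exp(β·PRS + covariate terms). Defaults
encode the study conditions the analysis is designed around: a per-unit-
normalized-PRS hazard ratio of 1.52 restricted to treated arms; an OS
hazard that drops by the factor 0.57 after hypothyroidism onset
(piecewise-exponential, a genuine time-dependent effect); gender and
baseline-TSH log hazard ratios 0.3 and 0.35 where enabled; baseline
thyroid-irAE hazards set so roughly 30% of treated and ~3% of control
patients develop hypothyroidism over follow-up, matching the event
proportions reported for checkpoint-inhibitor versus chemotherapy arms;
administrative censoring uniform on 400–1200 days. An optional
driver-variant subset routes the irAE hazard through a sub-score,
representing the hypothesis that only part of the lifetime-risk score
acts under treatment — the regime in which the survival lasso is
meaningful. Lab series place visits every 21 days, hold TSH in the normal
band before onset, suppress it below 0.4 during the hyperthyroid phase
and elevate it above threshold afterwards; among dual-event patients the
hyper-first ordering occurs with probability 0.857, and symptomatic
events fall at most 7 days after the first abnormal measurement. The
population-scale evaluation cohort plants a 0.48-SD case/control shift in
the normalised score — the value implied by inverting the power formula
at power 0.4, α = 0.01, 24 vs 819 — so the power computation is
recomputed rather than assumed.

One global integer seed fans out to named substreams per generator
(`numpy` SeedSequence with the stage name as spawn key), so each stage's
stream is isolated from the others' draw counts.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite within a half hour on one CPU: GWAS cohorts of 2000+2000 (8000 for
the conditional-analysis oracle and signal-count recovery), 200 variants
in 8 LD blocks, 200 simulated loci for credible-set coverage (drawn
directly from the LD-consistent multivariate normal for summary
statistics rather than 200 individual-level GWAS), trial cohorts of
1584 treated + 1302 control patients across 7+2 arms, lasso designs of
~1500 patients × 21 columns with 2-repeat cross-validation in tests
(the pipeline default remains 3-fold × 100 repeats), and 50 replicates
for sparsity-recovery rates.

## Known limitations

Single-character SNVs only (no indels); autosomal models only; the
conditional algebra assumes a shared sample size across variants; PPA is
computed within the locus window, so credible sets cannot extend past a
window edge; cumulative incidence ignores competing death; the lasso uses
Breslow ties inside coordinate descent (Efron is available in the
unpenalized engine); and the generators make no attempt at realistic
recombination maps, relatedness, or imputation noise.
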