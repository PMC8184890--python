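# prsurv

Fine-mapped polygenic risk scores and survival pharmacogenomics for
immune-related adverse events (irAE).

Checkpoint-inhibitor therapy frequently triggers thyroid autoimmunity:
hypothyroidism that appears during treatment, often preceded by a
transient hyperthyroid phase. `prsurv` implements, as a tested and
reusable pipeline, the analysis that links germline genetic risk of
lifetime hypothyroidism to these treatment-emergent events:

1. **Fine-mapping** — forward-selection approximate conditional analysis
   on GWAS summary statistics with an LD reference, then a 99% Wakefield
   credible set per conditionally independent signal from per-variant
   approximate Bayes factors

       r = W/(W+σ²),   z = β/σ,   ABF = √(1−r) · exp(z²r/2),
       PPAᵢ = ABFᵢ / Σₖ ABFₖ,     (W = 0.04)

2. **Scoring** — the PRS Ŝ = Σᵢ βᵢ·Gᵢ over each signal's max-PPA variant
   (Gᵢ = risk-allele dosage, βᵢ = conditional effect size), quantile-
   normalised to the standard normal.
3. **Survival analysis** — stratified Cox meta-analysis of the PRS
   against time-to-irAE across trial arms; irAE against overall survival
   with a time-dependent covariate (0 before onset, 1 after) that removes
   immortal-time bias; landmark analysis; Kaplan-Meier curves.
4. **Variant importance** — a non-negative L1-penalized Cox regression on
   dosage-times-effect-size columns (eigenvectors unpenalized), with the
   penalty chosen by repeated 3-fold cross-validation, identifying which
   score variants drive the association.
5. **Predictor evaluation** — PPV/sensitivity curves, cross-validated
   case/control effect sizes, analytic power, and composite risk-subgroup
   hazard ratios.

A synthetic-data module generates every input the pipeline consumes —
LD-blocked haplotypes, case-control cohorts, multi-arm trial outcomes
with PRS-dependent hazards, and longitudinal TSH lab series with the
hyperthyroidism-before-hypothyroidism clinical course — so the whole
chain is testable without any restricted data. Variant- and sample-level
QC (GQ masking, missingness, allele balance, Hardy-Weinberg, F-statistic
and iterative PCA outliers, tiered INFO/MAF panel filtering) is included.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

`examples/` holds one short script per capability. The survival stage
(`examples/03_trial_survival.py`) simulates 1584 treated patients across
7 arms plus 1302 controls with a planted per-unit-PRS irAE hazard ratio
of 1.52 and a planted post-irAE survival hazard ratio of 0.57, then
recovers both:

```
PRS -> irAE (stratified over 7 arms): HR 1.55 (95% CI 1.40-1.73), p = 2.68e-16  [planted 1.52]
  random-effects pooling: HR 1.55, tau^2 0.0141
irAE -> OS (time-dependent covariate): HR 0.55 (95% CI 0.44-0.67)  [planted 0.57]
150-day landmark: HR 0.46 (95% CI 0.32-0.65)
wrote trial_cuminc.png — higher-PRS patients accumulate events faster
```

The first line is the stratified Cox estimate of the hazard ratio per SD
of the normalised score among treated patients — the planted 1.52 sits
inside the interval. The time-dependent model shows that patients are at
roughly half the death hazard after thyroid-event onset, without the
immortal-time artefact a from-randomisation comparison would create.

The fine-mapping stage (`examples/02_finemap_and_score.py`) plants three
causal loci — one carrying two independent signals — and prints the
recovered credible sets and the resulting scoring file, e.g.:

```
locus chr1:6604000-7604000: 2 independent signal(s)
  signal 0: credible set of 3 variants, top rs105 (PPA 0.904, conditional beta 0.425)
  signal 1: credible set of 6 variants, top rs121 (PPA 0.615, conditional beta 0.364)
```

A thin CLI mirrors the library (`prsurv simulate | qc | gwas | ld |
harmonize | finemap | score | survival | landmark | events | lasso |
evaluate | run-all`, each with `--seed`, `--config`, `--out`); `run-all`
executes the full synthetic pipeline into a fixed artifact layout and is
byte-reproducible for a given seed.

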