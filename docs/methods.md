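# Methods

## Scope and model

`plskit` implements the analysis system around polygenic longevity scores
(PLS): score construction from variant-weight lists, the variant weight
overlap (VWO) statistic for comparing score definitions, a stratified
association battery against parental lifespan and disease, random-variant
null scores, and a synthetic biobank generator that supplies data with the
statistical structure those analyses assume. It does not re-derive
weights (GWAS and shrinkage methods such as PRS-CS are upstream; their
output weight lists are inputs here), does not impute genotypes, and does
not model linkage disequilibrium between scored variants — published
weight lists are assumed to have resolved LD already.

## Score construction

A score definition is a list of (variant, effect allele, other allele,
weight) rows. Harmonization against a dosage panel matches on
(chromosome, position, unordered allele pair) when coordinates are
present, otherwise on the variant identifier. Orientation is *direct*
when the definition's effect allele is the panel's counted allele and
*swapped* otherwise (the score then uses 2 − dosage). Definition variants
that are absent from the panel, carry a different allele pair, or are
strand-ambiguous (A/T, C/G; dropped by default) are removed and tallied
by reason — never substituted by proxies, which keeps the computed score
conservative and reproducible from the inputs alone.

Numerical choices:

* The score is the raw weighted **sum**. Some scoring tools divide by the
  number of counted alleles; that per-allele *average* is available via
  `convention="average"`. Every downstream analysis standardizes scores,
  so the convention cannot change any association.
* Missing dosages default to the variant's mean observed effect dosage
  (mean imputation keeps the score mean at its observed-data value);
  `zero` and `fail` policies are available.
* Quality filters are strict inequalities: info score > 0.8, MAF > 0.01.
  A variant exactly at a threshold is removed.
* Coordinates are 1-based, as in VCF.

## VWO

For definitions x and y, with T_x = Σ|w_{i,x}|:

    VWO(x, y) = Σ_{i ∈ x∩y} |w_{i,x} w_{i,y}| / (T_x T_y)

This is the canonical statistic: symmetric, scale-invariant in either
definition's weights, 0 for disjoint lists, 1 for two single-variant
lists sharing their variant, and bounded by 1 since Σ_{∩}|w_x w_y| ≤
T_x T_y. Note that two *identical* k-variant lists give Σ(|w_i|/T)² < 1
for k > 1: the statistic measures concentrated shared weight, not mere
identity. A non-canonical alternative (`variant="share_mean"`), the mean
of the two shared-weight fractions, reaches 1 for identical lists and is
provided for sensitivity analysis only; it is never used by default.

## Association battery

All lifespan analyses exclude adopted participants (their recorded
parents are not biological) and run per participant-sex × parent stratum
(plus pooled). Correlation, decile-contrast and linear analyses use dead
parents only, because an alive parent's eventual lifespan is unobserved;
the Cox model keeps alive parents as right-censored at their age at the
assessment date.

* **Correlations** — Pearson and Spearman with two-sided p-values.
* **Decile contrast** — Welch (unequal-variance) two-sample t test
  between individuals at or above the 90th score percentile and at or
  below the 10th. Membership is value-based (≥ / ≤ the quantile value),
  so a tied score value is never split across groups — important for
  scores built from a handful of variants, which take few distinct
  values. Overlapping tails raise an error describing the tie structure.
* **Linear model** — OLS of parental lifespan on the score with birth
  year, genotyping batch, assessment center (one-hot, first level as
  reference; degenerate columns dropped with a logged notice) and the
  first 40 genotype PCs. The score coefficient is in years per score
  unit.
* **Cox model** — partial likelihood (lifelines, Efron tie handling —
  appropriate since recorded ages tie heavily at integers) on the same
  covariates; protective scores give hazard ratios below 1.
* **Disease models** — logistic regression of case status on the PLS
  *co-adjusted for the disease-specific PRS*, age, sex and 40 PCs; both
  the PLS and PRS terms are reported. For single-sex diseases the sex
  column is omitted. Perfect separation raises an error suggesting the
  ridge-penalized fallback (small L2 penalty, intercept unpenalized,
  Wald intervals from the penalized Hessian), which must be requested
  explicitly.
* **COVID-death model** — logistic, restricted to the infected, on
  score, sex, birth year and 40 PCs (no batch/center).
* **Per-variant scan** — one OLS per variant (dosage as predictor) with
  birth year, batch and 10 PCs, computed by residualizing the outcome and
  all dosage columns against the shared covariates once
  (Frisch–Waugh–Lovell); this is algebraically identical to the full
  per-variant fits, and a test cross-checks it against statsmodels.
  Monomorphic variants are returned flagged rather than fitted.
* Raw p-values are reported throughout (no multiplicity adjustment by
  default), matching the battery's descriptive role; every result records
  the design columns actually used so the covariate contract is testable.

## Random-variant nulls

`make_random_score` replaces a fraction (1.0 or 0.5 in routine use) of a
definition's variants with random draws from the filtered panel — without
replacement, excluding variants already kept, weights retained in their
original order (the weight multiset is conserved). With an odd count,
50% replaces ⌈n/2⌉. Replacements take the panel's counted allele as
effect allele, and the draws are not frequency-matched to the originals.
`null_correlation_study` repeats randomize → score → correlate per parent
(unstratified by participant sex), ten iterations by default.
`pc_correlation_profile` correlates a score with each leading PC; the
profile of a random score provides the comparison band.

## Synthetic biobank generator

The generator emulates the *structure* the battery assumes, at sizes
chosen for desk-scale testing:

* **Genotypes** — per variant, an ancestral frequency uniform on
  [0.05, 0.95]; subpopulation frequencies from the Balding–Nichols beta
  construction with shape p(1−F)/F, (1−p)(1−F)/F (default F_ST = 0.05,
  two populations); dosages Binomial(2, p_pop) plus additive imputation
  noise (SD 0.05) clipped to [0, 2]. Info scores uniform on [0.5, 1];
  MAF recorded empirically; ~10% of variants are assigned palindromic
  allele pairs to exercise strand-ambiguity handling.
* **Causal architecture** — `n_causal` variants (default 50 of 500) with
  N(0, 1) weights define a latent score, standardized to mean 0, SD 1.
  Causal variants are drawn among filter-passing, non-palindromic
  variants so a truth-derived definition survives harmonization intact.
* **Lifespans** — parent lifespan = sex-specific mean (72 father / 78
  mother) + beta_pls × latent score (default 0.5 y/SD) + beta_birthyear ×
  centered parent birth year (0.05 y/y) + small batch/center effects
  (SD 0.2 y) + N(0, 10 y) noise, floored at 40 y. Lifespans are Gaussian
  around the linear predictor rather than Gompertz: the battery's linear
  and Cox models assume no particular hazard, and the Gaussian keeps
  recovery targets analytic. Participants are aged 40–69 at a fixed
  recruitment year; a parent is alive iff birth year + lifespan exceeds
  the assessment year, in which case their age at assessment is recorded
  and the vital flag set — so advancing the assessment year only
  converts alive to dead (censoring is monotone), and a far-future
  assessment yields a censoring-free design. The parent's lifespan
  depends on the *participant's* score directly, because that is the
  regression actually fitted (participant genotype vs parental outcome);
  an optional transmission flag halves the effect instead.
* **Diseases and COVID** — each disease is logistic in a latent N(0, 1)
  disease PRS (risk-increasing, default OR 1.5/SD), the latent longevity
  score (protective, default OR 0.8/SD), standardized age and sex;
  single-sex diseases carry missing indicators for the other sex. COVID
  infection is sampled at a configured fraction and death among the
  infected follows a logistic model with a protective longevity term
  (OR 0.8/SD).
* **Covariates** — genotype PCs are computed from the centered dosage
  matrix (randomized SVD, seeded); sex, birth year, batch, center,
  adoption flag (3%) and missing-parent records (2%) complete the table.
* **Determinism** — one integer seed feeds named substreams (panel,
  populations, causal, phenotypes, parents, diseases, covid, pca), so
  identical configurations reproduce byte-identical outputs and adding a
  generation stage never perturbs earlier draws.

What the generator deliberately does **not** emulate: LD between
variants, realistic age-specific mortality curves, relatedness, secular
trends in disease incidence, or genotype-call missingness patterns.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the stated generative model — not that any
particular real-cohort effect size is right.

## Verification design and problem sizes

* Scoring is verified against an explicit per-individual, per-variant
  loop (to 1e-10) including swapped orientations and missing dosages, on
  a 200 × 500 random panel; VWO against a brute-force evaluation of the
  formula on 1,000 random definition pairs (to 1e-12).
* Parameter recovery runs at n = 20,000 / 500 variants: linear beta
  within 3 SE of 0.5 y/SD, Cox HR < 1 with CI excluding 1, logistic
  recovery of OR 1.5 (PRS) and 0.8 (PLS) within 3 SE of their logs, and
  95% CI coverage within [0.90, 0.99] over 200 replicates at n = 5,000.
  Linear recovery and coverage use the censoring-free design
  (far-future assessment): conditioning on "parent already dead"
  truncates the Gaussian lifespan from above and attenuates the slope
  (by the truncated-normal factor E[1 − λ′], roughly 0.7 under the
  default censoring pattern), which is a property of the design, not an
  estimator defect. The Cox model is verified on the censored default
  design, where the partial likelihood handles alive parents correctly.
* Null calibration uses fully random scores on a null biobank
  (n = 1,500): empirical type-I error at α = 0.05 must lie in
  [0.03, 0.07] per model family (1,000 replicates for correlation,
  linear and logistic; 500 for Cox) with pooled null p-values passing a
  KS uniformity test; 50%-random scores must land strictly between the
  100%-random and real-score correlation magnitudes (50 iterations at
  n = 4,000, beta = 1 y/SD).
* The decile contrast has a closed form under the Gaussian generator:
  E[gap] = 2 × 1.7545 × beta × SD(score), 1.7545 being the mean of a
  standard normal beyond its 90th percentile. The check runs at
  n = 100,000 with beta = 1 y/SD and lifespan SD 5 y, chosen a priori so
  the Monte-Carlo SE of the gap (σ√(2/(qn)) ≈ 0.07 y) is several times
  smaller than the 5% tolerance band around the expected 3.51 y.
* The bundled demo configuration (800 × 300) runs every pipeline stage
  deterministically in seconds and is the end-to-end smoke check.

## Known limitations

* The per-variant scan mean-imputes missing dosages before
  residualization; with heavy missingness this slightly understates SEs.
* The ridge-penalized logistic fallback trades a small bias for finite
  estimates under separation; its Wald intervals are approximate.
* VWO compares definitions by shared *keys*; a variant present in two
  lists under different identifiers but without coordinates will not be
  matched.
* The generator's palindromic variants are generated with known strand,
  so strand-flip errors (as opposed to strand-ambiguity drops) are not
  simulated.
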