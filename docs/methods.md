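# Methods

## Substitution models and the interaction parameterization

Diet composition is a four-part composition in energy percent:
P + C + F + A = 100 (protein, carbohydrate, fat, alcohol). The closure
means a regression of an outcome on any three parts is implicitly a
substitution model: with the replaced macronutrient X omitted, the
coefficient on P is the effect of 1 E% protein replacing 1 E% of X at
fixed levels of the two included parts. Total energy is intentionally not
a covariate — changing relative protein intake may change total intake,
and the estimand is the effect of shifting composition with energy free
to move.

The same model is re-parameterized with the substitution variable
s = (P − X)/2 together with the kept macronutrient and alcohol.
Substituting X = 100 − P − kept − A shows the two designs span the same
column space with

- β_s = β_P,
- β_kept(sub) = β_kept(loo) − β_P/2,
- β_A(sub) = β_A(loo) − β_P/2,

identities the test suite asserts to 1e-8 relative error along with
equality of fitted values. The point of the re-parameterization is the
interaction: s × G (G a predisposition score) is a *substitution-specific*
interaction term, whereas P × G would test a protein-in-itself interaction
independent of what protein replaces.

### Adjustment set and encodings

Models adjust for the baseline level of the outcome, height, sex, smoking
(never/former/current), physical activity (4 ordered groups), education
(low/high) and menopausal status; ΔWC models additionally adjust for
concurrent ΔBW to isolate waist change beyond overall mass change.
Categorical covariates are indicator-coded against the first level.
Menopausal status is conceptually a three-level factor (male / pre /
post); because the male level is exactly the complement of the sex
indicator, the design encodes it as `sex_female` + `menopause_post`,
which spans the identical column space at full rank. Age and follow-up
time are config-exposed adjustments, both off by default; the default
adjustment set is the one the anthropometric-change models were defined
with. Rows are complete cases per model fit and the attrition count is
logged and carried in every result row.

Compositions whose E% sum deviates from 100 by more than 0.5 E% (the
configurable tolerance) are renormalized to 100 with a warning; negative
components are an error.

## Scores

Predisposition scores are unweighted risk-allele counts over a SNP subset
selected by trait tag; the complete score sums all 50 panel SNPs directly.
Subset sizes (33/6/14) are read from the panel file, never hard-coded, and
the tags overlap (33 + 6 + 14 = 53 > 50), so the complete score is not the
sum of the three subset scores. Complete-case scoring (any missing dosage
⇒ missing score) reproduces the attrition pattern in which the complete
score has the smallest analyzable N. The bundled panel carries placeholder
rsIDs (plus five literature-known BMI loci) and plausible allele
frequencies chosen so the mean complete score is ≈ 44; real analyses
supply their own panel TSV.

The mean split used by the subgroup analysis labels scores strictly above
the within-cohort mean "high"; a score exactly at the mean goes to "low"
(the source convention "above or below the mean" leaves ties undefined, so
the rule is documented here and deterministic).

## Outcomes, energy balance, gainer selection

Annualized changes are (follow-up − baseline)/follow-up years, kg/y and
cm/y internally; reporting multiplies by 1000 (g/y) or 10 (mm/y) and by 5
for per-5 E% effects, leaving z-statistics invariant. Energy balance is
trichotomized at ±0.5 kg/y with the boundary included in "neutral" (the
consistent reading of a ±0.5 bracket with strict > 0.5 tails). Protein in
g/kg/day converts via 17 kJ per gram of protein and baseline body weight;
both choices are config-exposed (`longitudinal.KJ_PER_G_PROTEIN`).

Weight-gainer selection (for case-cohort emulation) regresses annual
weight change on baseline age, weight, height, smoking and follow-up time
within each sex and takes the top-k residuals, ties broken by individual
id. Selection is invariant to adding any linear function of those
covariates to the outcome, which the tests assert.

## Inference

Fits are OLS with classical standard errors. CIs and p-values use normal
quantiles (1.959964) by default with a t switch for small samples; at
cohort sizes in the thousands the difference is far below reporting
precision, and the printed CIs round-trip exactly under the normal
quantile. Rank deficiency is diagnosed by pivoted QR and reported with
the offending column names; constant indicator columns (a level absent
from a cohort) are dropped with a warning before the rank check.

## Meta-analysis

Fixed-effect weights are 1/se²; Q, I² and the DL τ² are computed on those
weights (classic non-iterated DL, not Paule–Mandel — the variant whose
weights match the published tables to 0.01), and random-effects weights
are 1/(se² + τ²). Single-study input degenerates to a passthrough with
τ² = 0. Standard errors recovered from printed CIs use se = (hi − lo) /
(2 × 1.959964). I² bands are half-open upward ([0,25) none, [25,50)
moderate, [50,75) significant, [75,100] extreme); a boundary value takes
the higher band. A near-zero pooled estimate is printed at full precision
(no "<0.1"-style display conventions). The implementation is cross-checked
in the tests against `statsmodels.stats.meta_analysis.combine_effects`,
which is never used as the implementation.

## Per-SNP scan

Each panel SNP's dosage replaces the score in the interaction model, one
fit per SNP; the Bonferroni multiplier stays at the panel size (50) even
when individual SNPs are skipped (e.g. monomorphic in a cohort), because
the test family is defined by the panel. Correction is applied within
each outcome × substitution combination, and the output carries `m_tests`
so a joint correction can be reconstructed.

## Synthetic cohorts

The generator mirrors the analysis model, which is exactly what makes it
useful for calibration testing and exactly what limits it:

- **Genotypes**: dosage ~ Binomial(2, p) per SNP (HWE), independent across
  SNPs (no LD), with a 1% independent genotyping-failure rate — consistent
  with per-SNP call rates around 99% and with roughly half to two-thirds
  of individuals retaining a complete 50-SNP score.
- **Diet**: logistic-normal composition — Gaussian noise on the log-ratios
  of C, F, A against P, closed to 100 — chosen over a Dirichlet because it
  allows realistic correlations and heavy right-skew for alcohol
  (log-ratio SDs 0.25/0.30/1.20). Cohort presets centre the composition on
  the three cohorts' median profiles (protein 14.0/17.7/14.8 E%); total
  energy is lognormal with median 9 MJ/d.
- **Outcomes**: d_bw = β₀ + β_sub·s + β_G·G + β_int·s·G + covariate terms
  + N(0, σ), with defaults β_sub = 0.0082 kg/y per E% (the pooled
  observed magnitude), β_G = β_int = 0 (the null findings) and σ = 0.9
  kg/y (matching observed 5–95% ranges of annual change). Waist change
  couples to weight change at 1 cm/kg plus its own noise so the
  ΔBW-adjustment pathway is exercised. Follow-up weight is back-computed
  as bw0 + d_bw × follow-up.
- **Cohort presets** reproduce structural quirks: the MONICA-like preset
  lacks waist data entirely; the DCH-like preset draws a larger pool and
  mixes top-600-per-sex residual weight gainers with a random sample.

Not emulated: measurement error in food records/FFQs and self-reported
follow-up anthropometry, desirability bias, LD between SNPs, real
covariate correlation structure (covariates are independent draws matching
category frequencies). Passing calibration tests therefore demonstrates
the estimator's correctness under the assumed model, not robustness to
those real-data features.

## Calibration results and problem sizes

The repeated-simulation check (`simulate.recovery_experiment`) uses 200
replicates of three n = 2000 cohorts with a planted interaction of 0.002
kg/y per E% per allele: the pooled DL estimate is unbiased within
Monte-Carlo error (two-sided 5% z-test) and 95% CI coverage lies in
[92, 98]%; 100 matching null replicates give a median I² below 25. These
sizes give stable Monte-Carlo behaviour at interactive runtimes; the
interaction SE at that size (≈ 3 g/y per 5 E% per allele, pooled) brackets
the published precision. Unit tests use smaller cohorts (n = 250–600)
where only structural behaviour, not calibration, is asserted.

## Numerical conventions

- Normal quantile 1.959964 throughout CI ↔ SE conversions.
- Rank decisions use `numpy.linalg.matrix_rank`'s default SVD tolerance;
  collinearity naming uses pivoted QR with an eps-scaled threshold.
- Random state: every stochastic entry point takes an explicit seed;
  multi-cohort runs derive child seeds via `numpy.random.SeedSequence`
  (kept below 2³¹). Same seed ⇒ bit-identical datasets and output files.
- Pipeline outputs are TSV plus a JSON manifest (package version, seed,
  config hash); reruns with identical config and seed are byte-identical.
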