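# Methods

## The frailty index

The deficit-accumulation frailty index treats health deficits — diseases,
symptoms, disabilities, abnormal measurements — as interchangeable counters.
Each item is coded to [0, 1] (0 = absent, 1 = fully expressed) and the index
is the coded sum divided by the number of non-missing items. The package
implements the two standard coding regimes side by side:

- **ordinal**: multi-level responses receive intermediate values on a
  `k/(K−1)` grid (e.g. 0, 0.5, 1; 0, 0.25, 0.5, 0.75, 1), and measured
  variables are binned into graded severities;
- **dichotomous**: every item collapses to presence/absence, 0 or 1.

Missing items shrink the denominator; no imputation is performed. An
individual missing strictly more than the threshold (default 20%) of the
items is excluded. The strict inequality is deliberate: an individual
missing exactly 20% is retained. The missing fraction is taken over the
coding book's full item count, not over the items that happened to be
encodable for that individual.

When both regimes are compared, exclusion is harmonized: anyone over the
threshold under *either* coding is dropped from both, so all paired
contrasts (means, HRs, AUCs) describe a common individual set.

## Coding books

A `CodingSchema` holds, per variable, an ordinal and a dichotomous map —
either a categorical `LevelMap` (response label → value, declared in
severity order) or a `NumericBinMap` (contiguous intervals over the
measurement range, optionally sex-specific). Three complete study coding
books are packaged (23-, 70- and 33-variable batteries from population
cohort studies of adults 18+, 50+ and 70+), each in two variants.

Numeric bins required conventions the source tables do not state:

- Intervals carry explicit open/closed flags per boundary, defaulting to
  closed-left/open-right; validation requires that every interior boundary
  belong to exactly one bin, so assignment is total and deterministic.
  Printed `≤c / >c` cutoffs (gait times, peak flow, grip/shoulder strength
  dichotomies) keep the boundary in the lower bin, as printed.
- Where adjacent printed bins overlap at a point (systolic blood pressure
  "90–140" then "140–160"), the shared value goes to the higher bin
  (closed-left); where a printed range is followed by a strict ">" (e.g.
  "140–160" then ">160"), the boundary stays in the lower bin.
- Gaps between printed bins of integer-valued or coarsely printed scales
  (MMSE "21–24" vs ">25"; peak flow "<310" vs "311–407"; decimal gait and
  strength bins) are closed by extending the adjacent lower-severity bin, so
  every real measurement maps to a value.
- The MMSE dichotomy ">24 = 0, <24 = 1" leaves 24 unassigned; 24 is coded
  non-deficit, matching the conventional 24-point cutoff.
- Values printed as 0.333/0.666 are stored as exact thirds.
- Each numeric map declares its clinical `direction` — `increasing` (larger
  measurement is worse: gait time, LDL), `decreasing` (larger is better:
  peak flow, strength, cognitive scores), or `range` (healthy mid-range with
  deficits on both tails: blood pressure, BMI). Validation checks the value
  sequence against the declared direction; a `range` map may fall and then
  rise once. Two published rows violate their direction (a delayed-recall
  scale whose fourth level repeats 0.25, and a women's strength coding whose
  best-performance bin is printed as a full deficit); the `as_printed`
  variants ship them verbatim and flag them as warnings, the `corrected`
  variants repair them (0.25 → 0.75; top bin → 0). Responses such as
  "don't know"/"refused" are declared missing labels, not deficits.

A variable's level count is the number of severity grades of its ordinal
map: the number of declared levels/bins for label maps and monotone bin
maps; for `range` maps the two tails reach the same grades, so the count is
the number of distinct values (blood pressure coded 0.5/0/0.5/1 is a 3-level
variable). This reproduces the documented battery compositions
({2:19, 3:2, 4:1, 5:1}, {2:60, 3:1, 4:2, 5:7}, {2:12, 3:14, 4:1, 5:6}).

Unrecognized response labels are coded missing and tallied per item in the
returned matrix — data loss is visible but never fatal.

### Item screening

The screening report operationalizes the standard selection criteria
advisorily (it never drops variables): missing fraction against a 5%
threshold; saturation as prevalence of the dichotomous deficit among
individuals aged 80+ (flagged above 80%, reported as not assessable when the
cohort has nobody that old); age-association as a two-sided Spearman rank
test of the coded value against age at α = 0.05 (rank correlation is used
because deficits are ordinal; an inestimable correlation counts as not
age-related).

## Synthetic cohorts

The generator exists so the whole pipeline can be tested with known truth;
it makes no claim of reproducing any real cohort's microdata.

- **Liability.** `L_i = α0 + α1·(age_i − age_lo) + s·female_i + u_i`,
  `u_i ~ N(0, σ²)`, σ = 1. A single latent liability is the simplest
  structure that reproduces the stylized facts an FI shows in real data: it
  rises with age, is higher in women, and predicts death.
- **Items.** Item *j* with K levels responds at level
  `#{k : λ_j L_i + e_ij > τ_jk}` with standard-logistic `e_ij` — the graded
  response model. Ordinal value = level/(K−1); dichotomous value = 1 iff the
  level reaches the item's cut. Both encodings collapse the same draw, so
  they are consistent at the source.
- **Mortality.** Gompertz hazard
  `h_i(t) = h0 · e^{γt} · exp(β_FI·100·FI_i + β_age·age_i + β_sex·female_i)`
  sampled by inversion of the closed-form integrated hazard
  (`T = log1p(γE/a)/γ`, `E ~ Exp(1)`), censored administratively at the
  follow-up horizon. The log-linear covariates make proportional hazards
  exactly true, so Cox recovery is well-posed; `FI_i` is the true ordinal FI
  over all items before missingness, making β_FI a log-HR per 0.01 FI.
- **Missingness** is completely at random at a per-cell rate (presets: 2%,
  a typical survey item-nonresponse level).

### Presets

`nshs_like`, `share_like` and `yale_like` fix the item compositions
(23/70/33 items with the level mixes above), age distributions (truncated
normals: 18–99 mean 48.1 SD 19.8; 50–99 mean 64.2 SD 10.5; 70–99 mean 78.4
SD 5.3), female fractions (0.501/0.56/0.646) and follow-up horizons
(10/5/12.9 years) of the three emulated studies. Item thresholds are drawn
once from a preset-internal seed (first thresholds uniform on 0.5–3.5
logits, later thresholds at gaps of 0.6–1.2), giving deficit prevalences
from common to rare; discriminations are 1; polytomous items dichotomize at
their middle level. Liability slopes (0.03–0.04 per year) put mean FI near
0.15–0.19 and rising across age decades.

Hazard parameters: β_FI = log 1.04 per 0.01 FI in all presets; direct age
effects of log 1.08–1.10 per year and female effects of log 0.50–0.65, in
the range such cohorts report; Gompertz slope 0.09/yr. Baseline hazards
(1.2e-5, 6.1e-5, 8.7e-5 per year) were set once so the presets land near
the emulated studies' overall death fractions (~12%, ~12%, ~73%); these are
rough design anchors, not calibration targets, and the presets make no
claim of matching the originals beyond structure.

What passing tests on these cohorts do *not* show: robustness to informative
missingness, competing risks, country/survey weighting, longitudinal deficit
trajectories, or items that violate the single-liability structure. Real
cohorts have all of these.

## Validation statistics

- **ANOVA.** Scores of both schemes are stacked and modelled as
  `score ~ scheme + sex` (two-way fixed effects, no interaction); the
  scheme-factor p-value is reported with raw cell means and sex-adjusted
  scheme means (cell means averaged over sex with equal weight). This
  independent-groups form ignores that the two schemes score the same
  people; a paired t-test p-value on the per-individual differences is
  emitted alongside as a clearly-labelled diagnostic. Both raw stratum means
  and model-adjusted means are available, since either convention is common.
- **Cox regression.** Partial-likelihood fit (lifelines) on 100·FI, age in
  years, and a female indicator. HRs are reported per 0.01 FI — the only
  scale on which frailty HRs near 1.03–1.05 are interpretable — with the
  per-0.10 scale as a secondary accessor. Proportionality is assessed per
  covariate by the scaled Schoenfeld-residual trend test (rank transform) at
  α = 0.05 and reported as an advisory flag; it never aborts a fit. Zero
  events is an error, never a silent result.
- **ROC AUC.** Tie-corrected concordance computed from midranks with a
  single final division, which makes it bit-identical to exhaustive
  case–control pair enumeration (ties = ½). The variance is the DeLong
  placement-value (two-sample U-statistic) estimator; the 95% CI is the
  normal approximation clipped to [0, 1], chosen over the bootstrap for
  determinism. The outcome is death within the follow-up window; individuals
  censored earlier count as non-deaths, as a fixed-horizon mortality linkage
  implies — a logged limitation, not a modelling choice.
- **Paired report.** Deltas are absolute differences of sex-adjusted means
  (also translated into deficit units by multiplying by the item count —
  exact arithmetic), of FI hazard ratios, and of AUCs (pooled and per sex).

## Problem sizes and tolerances

The test suite checks the FI against an independent per-individual loop to
1e-12 on random matrices up to 500×70; AUC against brute-force enumeration
exactly on instances up to n = 200; Cox CI coverage of the generating HR
over 20 replicates of n = 2000 (binomial band ≥15/20); the
scheme-agreement property over 20 seeds of n = 5000; ANOVA null calibration
over 1000 permutation replicates of a 400-person cohort (accepting 3–7%
rejection at nominal 5%); and screening flags over 20 seeds of n = 2000.
These sizes give each stochastic check a comfortable margin while keeping
the full suite to roughly half a minute of CPU.

## Known limitations

- Missingness is MCAR only; the exclusion rule's behaviour under informative
  missingness is untested.
- The ROC outcome ignores censoring before the horizon (no IPCW correction).
- The ANOVA's independent-groups form is anti-conservative in principle for
  paired scores; the paired diagnostic is provided, and the permutation
  calibration covers the independent-groups use.
- Sex is modelled as binary male/female because the coding books'
  sex-specific bins (peak flow, shoulder strength) are published that way.
- The synthetic generator's single-liability assumption makes ordinal and
  dichotomous FIs more exchangeable than adversarial real data could be;
  the packaged coding books, not the simulator, are the ground truth for
  coding behaviour.
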