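# frailtyindex

Deficit-accumulation frailty indices under ordinal and dichotomous coding,
with the statistical machinery to compare the two regimes.

## The problem

A frailty index (FI) quantifies the health status of an ageing individual as
the proportion of age-related health deficits present out of all deficits
considered:

```
FI_i = (Σ_j x_ij over non-missing items) / m_i,        x_ij ∈ [0, 1]
```

where `x_ij` codes deficit *j* for individual *i* (0 = absent, 1 = fully
expressed) and `m_i` is the number of non-missing items. Individuals missing
strictly more than 20% of the items are excluded rather than imputed.

Every variable that goes into an FI must be mapped onto [0, 1], and there are
two natural ways to do it: **dichotomous** coding marks presence/absence
(0 or 1), while **ordinal** coding grades severity (e.g. 0, 0.5, 1 for
"no / yes with assistance / no, cannot"). Whether the choice matters — for
mean index levels, sex differences, and mortality prediction — is an
empirical question this package lets you ask of any cohort, and answer on
synthetic cohorts with known generating parameters.

The package is aimed at epidemiologists and biostatisticians building or
validating frailty indices from survey/cohort data, and at methodologists
studying the robustness of deficit-accumulation scoring.

## What is in the box

- **Coding books** (`frailtyindex.schema`): categorical level maps and
  numeric bin maps (optionally sex-specific), loadable from JSON/YAML, with
  structural validation and monotonicity diagnostics. Three complete study
  coding books are packaged — `nshs` (23 variables), `share` (70),
  `yale_pep` (33) — each in an `as_printed` variant transcribing the
  published tables verbatim (including two internally inconsistent rows,
  which the validator flags) and a `corrected` variant repairing them.
- **Scoring engine** (`frailtyindex.engine`): vectorized encoding of raw
  responses, FI computation with the >20%-missing exclusion rule, and an
  advisory item-screening report (missingness ≤5%, non-saturation — deficit
  present in ≤80% of people aged 80+ — and age-association by Spearman rank
  test).
- **Synthetic cohorts** (`frailtyindex.simulate`): a graded (ordered-logistic)
  response model on a shared age-linked latent liability, with Gompertz
  mortality driven by the true ordinal FI (HR 1.04 per 0.01 FI in the
  presets), plus a Cox parameter-recovery harness. Presets `nshs_like`,
  `share_like`, `yale_like` mirror the three studies' item compositions, age
  distributions, sex ratios and follow-up horizons.
- **Validation statistics** (`frailtyindex.stats`): sex-adjusted two-way
  ANOVA for scheme differences in mean FI, multivariable Cox regression
  (FI per 0.01, age, sex) with scaled Schoenfeld proportionality
  diagnostics, tie-corrected ROC AUC with a DeLong placement-value CI, and
  the paired comparison report.
- **Model interface** (`frailtyindex.model`): `FrailtyComparison(...).fit()`
  returns a results object with `summary()`, per-individual scores, and a
  report bundle writer; `frailtyindex.cli` exposes the same pipeline as the
  `frailty-index` command (`build-fi`, `simulate`, `compare`, `screen`,
  `validate-schema`).

## Worked example

```python
import frailtyindex as fx

model = fx.FrailtyComparison.from_preset("share_like", n=2000, seed=7)
res = model.fit()
print(res.summary())
```

```
==============================================================================
Frailty index comparison — cohort 'share_like', 70 items
==============================================================================
individuals read 2000, scored 2000, excluded (> 20% items missing under either coding) 0; deaths 226

Mean FI (SD) and ROC area (95% CI) by scheme and sex
------------------------------------------------------------------------------
scheme       sex      mean FI (SD)      AUC (95% CI)
ordinal      female   0.183 (0.137)     0.745 (0.698, 0.792)
ordinal      male     0.149 (0.118)     0.752 (0.705, 0.799)
dichotomous  female   0.187 (0.140)     0.744 (0.696, 0.791)
dichotomous  male     0.152 (0.121)     0.750 (0.702, 0.797)

sex-adjusted means: ordinal 0.1659, dichotomous 0.1697 (ANOVA scheme p = 0.365)

Cox proportional hazards (time to death)
------------------------------------------------------------------------------
scheme       covariate          HR              95% CI           p
ordinal      fi_per_0.01     1.047      (1.038, 1.055)    1.15e-28
ordinal      age             1.080      (1.064, 1.097)    2.01e-24
ordinal      female          0.622      (0.477, 0.812)    0.000465
dichotomous  fi_per_0.01     1.046      (1.038, 1.054)    9.73e-29
dichotomous  age             1.081      (1.065, 1.097)    1.63e-24
dichotomous  female          0.622      (0.477, 0.811)    0.000463

Paired differences (ordinal vs dichotomous)
------------------------------------------------------------------------------
|d mean FI| = 0.0037 (0.26 deficits of 70)
|d HR per 0.01 FI| = 0.0008
|d AUC| = 0.0014 (male 0.0024, female 0.0014)
==============================================================================
```

Reading the output: a 2000-person cohort emulating a European ageing survey
was generated with a true mortality hazard ratio of 1.04 per 0.01 FI; the
fitted HR is 1.047 (CI 1.038–1.055) under either coding. Women carry higher
FI values but lower mortality hazard, FI predicts 5-year death with AUC
≈ 0.75, and the two coding regimes differ by 0.004 in mean FI (about a
quarter of one deficit out of 70), 0.0008 in HR, and 0.0014 in AUC — the
coding choice is immaterial here.

The same pipeline runs on real delimited-text cohorts:

```bash
frailty-index compare --cohort cohort.csv --survival survival.csv \
    --study share --variant corrected --out report/
```

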