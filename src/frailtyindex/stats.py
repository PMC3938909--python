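"""Comparison machinery for ordinal vs dichotomous frailty indices.

Four pieces mirror a standard index-validation workflow:

* :func:`mean_fi_anova` — sex-adjusted mean FI per coding scheme and the
  scheme-difference p-value from a two-way fixed-effects ANOVA;
* :func:`cox_mortality` — multivariable Cox regression for time to death
  (FI per 0.01, age in years, female indicator) with a scaled
  Schoenfeld-residual proportionality diagnostic;
* :func:`roc_auc` — tie-corrected AUC for mortality with a DeLong
  (placement-value) variance and normal-approximation CI;
* :func:`compare_indices` — the paired ordinal-vs-dichotomous report:
  means, HRs, AUCs and their absolute differences, including the
  deficit-unit translation |delta mean FI| * n_items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "CoxResult",
    "AucResult",
    "SchemeReport",
    "ComparisonReport",
    "mean_fi_anova",
    "cox_mortality",
    "roc_auc",
    "roc_curve_points",
    "build_scheme_report",
    "compare_indices",
]

_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# ANOVA on mean FI
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Sex-adjusted scheme means and the ANOVA scheme-difference test."""

    cell_means: pd.DataFrame          # scheme x sex raw means/SD/n
    adjusted_means: dict[str, float]  # sex-adjusted (equal-weight LS) means
    p_scheme: float
    anova_table: pd.DataFrame
    p_paired: float                   # diagnostic paired t-test (non-ANOVA)
    n: int

    @property
    def delta_adjusted_mean(self) -> float:
        a, b = self.adjusted_means.values()
        return abs(a - b)


def mean_fi_anova(
    fi_ord: pd.Series,
    fi_dich: pd.Series,
    sex: pd.Series,
    labels: tuple[str, str] = ("ordinal", "dichotomous"),
    sex_dich: pd.Series | None = None,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of stacked FI scores on scheme + sex.

    Both schemes must score the same individuals; rows where either score is
    missing are dropped pairwise.  Returns raw cell means, sex-adjusted
    scheme means (cell means averaged over sex with equal weight), and the
    scheme-factor p-value.  A paired t-test p-value on the per-individual
    score differences is attached as a diagnostic — the ANOVA ignores the
    paired structure by design.

    ``sex_dich`` supplies a separate sex vector for the second group when the
    two score vectors do not describe the same individuals (permutation
    nulls, stratified designs); the paired diagnostic is then meaningless
    and reported as NaN.
    """
    paired = sex_dich is None
    if sex_dich is None:
        sex_dich = sex
    fi_ord, fi_dich, sex, sex_dich = (
        pd.Series(x).reset_index(drop=True)
        for x in (fi_ord, fi_dich, sex, sex_dich)
    )
    if not (len(fi_ord) == len(fi_dich) == len(sex) == len(sex_dich)):
        raise ValueError("fi_ord, fi_dich and sex must have equal length")
    keep = fi_ord.notna() & fi_dich.notna() & sex.notna() & sex_dich.notna()
    fi_ord, fi_dich, sex, sex_dich = (
        fi_ord[keep], fi_dich[keep], sex[keep], sex_dich[keep]
    )
    n = len(fi_ord)
    if n < 3:
        raise ValueError(f"need at least 3 scored individuals, have {n}")
    sexes = sorted(set(sex.unique()) | set(sex_dich.unique()))
    if len(sexes) < 2:
        raise ValueError("both sexes must be present for a sex-adjusted ANOVA")

    stacked = pd.DataFrame(
        {
            "score": pd.concat([fi_ord, fi_dich], ignore_index=True),
            "scheme": [labels[0]] * n + [labels[1]] * n,
            "sex": pd.concat([sex, sex_dich], ignore_index=True),
        }
    )
    model = smf.ols("score ~ C(scheme) + C(sex)", data=stacked).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_scheme = float(table.loc["C(scheme)", "PR(>F)"])
    if math.isnan(p_scheme):  # zero scheme and residual variation
        p_scheme = 1.0

    cells = (
        stacked.groupby(["scheme", "sex"], observed=True)["score"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )
    pred = model.predict(
        pd.DataFrame(
            [(s, x) for s in labels for x in sexes], columns=["scheme", "sex"]
        )
    ).to_numpy()
    k = len(sexes)
    adjusted = {
        labels[0]: float(pred[:k].mean()),
        labels[1]: float(pred[k:].mean()),
    }
    if not paired:
        p_paired = float("nan")
    else:
        diffs = fi_ord.to_numpy() - fi_dich.to_numpy()
        if np.allclose(diffs.std(ddof=1) if n > 1 else 0.0, 0.0):
            p_paired = 1.0 if np.allclose(diffs, 0.0) else 0.0
        else:
            p_paired = float(sps.ttest_rel(fi_ord, fi_dich).pvalue)
    return AnovaResult(
        cell_means=cells,
        adjusted_means=adjusted,
        p_scheme=p_scheme,
        anova_table=table,
        p_paired=p_paired,
        n=n,
    )


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """HRs, CIs and proportionality diagnostics for one fitted FI scheme."""

    summary: pd.DataFrame       # per covariate: coef, hr, CI, p
    proportionality: pd.DataFrame  # per covariate: test stat, p, flag
    n: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False)

    @property
    def hr_fi(self) -> float:
        return float(self.summary.loc["fi_per_0.01", "hr"])

    @property
    def hr_fi_per_0_10(self) -> float:
        """Secondary scale: HR per 0.10 FI."""
        return float(math.exp(10 * self.summary.loc["fi_per_0.01", "coef"]))


def cox_mortality(
    fi: pd.Series,
    survival: pd.DataFrame,
    extra_covariates: pd.Series | pd.DataFrame | None = None,
    alpha_ph: float = 0.05,
) -> CoxResult:
    """Cox regression of time to death on FI (per 0.01), age and sex.

    ``survival`` needs columns ``time`` (years, > 0), ``event`` (1 = died),
    ``age`` and ``sex``, indexed like ``fi``.  Hazard ratios are reported per
    0.01 FI — the conventional reporting scale for frailty indices (use
    :attr:`CoxResult.hr_fi_per_0_10` for the per-0.10 scale).
    Proportionality is assessed per covariate with the scaled
    Schoenfeld-residual trend test; violations are advisory flags, the fit is
    never aborted.
    """
    from .engine import normalize_sex

    df = pd.DataFrame(
        {
            "time": pd.to_numeric(survival["time"], errors="coerce"),
            "event": pd.to_numeric(survival["event"], errors="coerce"),
            "fi_per_0.01": 100.0 * pd.Series(fi).reindex(survival.index),
            "age": pd.to_numeric(survival["age"], errors="coerce"),
            "female": (normalize_sex(survival["sex"]) == "female").astype(float),
        },
        index=survival.index,
    )
    if extra_covariates is not None:
        extra = pd.DataFrame(extra_covariates)
        df = df.join(extra)
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        df = df.dropna()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("zero events: no deaths observed")

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_ci_low": s["exp(coef) lower 95%"],
            "hr_ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.index.name = "covariate"

    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_df = ph.summary.copy()
    ph_df["non_proportional"] = ph_df["p"] < alpha_ph
    return CoxResult(
        summary=out,
        proportionality=ph_df,
        n=len(df),
        n_events=n_events,
        fitter=cph,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores, outcome) -> AucResult:
    """Tie-corrected AUC with a DeLong placement-value variance.

    The AUC is the probability that a randomly chosen case (death) outscores
    a randomly chosen control, ties counting one half — computed exactly via
    midranks.  The variance combines the per-case and per-control placement
    variances (the two-sample U-statistic estimator); the 95% CI is the
    normal approximation clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(bool)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must have equal length")
    ok = ~np.isnan(scores)
    scores, outcome = scores[ok], outcome[ok]
    m = int(outcome.sum())
    n = int((~outcome).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")

    pos, neg = scores[outcome], scores[~outcome]
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    # single final division: the numerator is an exact multiple of 1/2, so
    # this matches exhaustive pair counting bit-for-bit
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values (DeLong structural components)
    v01 = (tz[:m] - tx) / n            # per case
    v10 = 1.0 - (tz[m:] - ty) / m      # per control
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = math.sqrt(var)
    return AucResult(
        auc=float(auc),
        se=se,
        ci_low=float(max(0.0, auc - _Z95 * se)),
        ci_high=float(min(1.0, auc + _Z95 * se)),
        n_cases=m,
        n_controls=n,
    )


def roc_curve_points(scores, outcome) -> pd.DataFrame:
    """ROC curve coordinates (threshold, FPR, TPR) for plotting."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    ok = ~np.isnan(scores)
    fpr, tpr, thr = roc_curve(outcome[ok], scores[ok])
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# paired comparison report
# ---------------------------------------------------------------------------


@dataclass
class SchemeReport:
    """All single-scheme results needed for the paired comparison."""

    scheme: str
    fi: pd.Series
    cox: CoxResult
    auc: AucResult
    auc_by_sex: dict[str, AucResult]
    means_by_sex: pd.DataFrame


def build_scheme_report(
    scheme: str, fi: pd.Series, survival: pd.DataFrame
) -> SchemeReport:
    """Fit the full single-scheme battery (Cox, pooled and per-sex AUC)."""
    from .engine import normalize_sex

    fi = pd.Series(fi).reindex(survival.index)
    sex = normalize_sex(survival["sex"])
    died = survival["event"].astype(bool)
    cox = cox_mortality(fi, survival)
    auc = roc_auc(fi, died)
    auc_by_sex = {}
    for sx in ("male", "female"):
        sel = (sex == sx).to_numpy()
        if sel.any() and died[sel].nunique() == 2:
            auc_by_sex[sx] = roc_auc(fi[sel], died[sel])
    means = (
        pd.DataFrame({"fi": fi, "sex": sex})
        .dropna()
        .groupby("sex", observed=True)["fi"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )
    return SchemeReport(
        scheme=scheme,
        fi=fi,
        cox=cox,
        auc=auc,
        auc_by_sex=auc_by_sex,
        means_by_sex=means,
    )


@dataclass
class ComparisonReport:
    """Paired ordinal-vs-dichotomous summary with absolute deltas."""

    ordinal: SchemeReport
    dichotomous: SchemeReport
    anova: AnovaResult
    n_items: int
    delta_mean_fi: float       # |difference of sex-adjusted means|, FI units
    delta_mean_deficits: float  # the same difference in deficit counts
    delta_hr_fi: float
    delta_auc: float
    delta_auc_by_sex: dict[str, float]

    def to_dict(self) -> dict:
        """Machine-readable form of the full report."""
        def scheme_block(r: SchemeReport) -> dict:
            return {
                "means_by_sex": r.means_by_sex.reset_index().to_dict("records"),
                "cox": r.cox.summary.reset_index().to_dict("records"),
                "hr_fi_per_0.01": r.cox.hr_fi,
                "hr_fi_per_0.10": r.cox.hr_fi_per_0_10,
                "proportionality": r.cox.proportionality.reset_index(
                    drop=True
                ).to_dict("records"),
                "auc": vars(r.auc).copy(),
                "auc_by_sex": {s: vars(a).copy() for s, a in r.auc_by_sex.items()},
                "n": r.cox.n,
                "n_events": r.cox.n_events,
            }

        return {
            "n_items": self.n_items,
            "anova": {
                "adjusted_means": self.anova.adjusted_means,
                "p_scheme": self.anova.p_scheme,
                "p_paired_diagnostic": self.anova.p_paired,
                "n": self.anova.n,
            },
            "deltas": {
                "mean_fi": self.delta_mean_fi,
                "mean_deficits": self.delta_mean_deficits,
                "hr_fi": self.delta_hr_fi,
                "auc": self.delta_auc,
                "auc_by_sex": dict(self.delta_auc_by_sex),
            },
            "ordinal": scheme_block(self.ordinal),
            "dichotomous": scheme_block(self.dichotomous),
        }


def compare_indices(
    report_ord: SchemeReport,
    report_dich: SchemeReport,
    n_items: int,
    anova: AnovaResult | None = None,
    sex: pd.Series | None = None,
) -> ComparisonReport:
    """Assemble the paired comparison from two single-scheme reports.

    Both reports must score the same individuals.  The mean-FI delta uses the
    sex-adjusted ANOVA means; its deficit-unit translation is exactly
    ``delta * n_items``.
    """
    if not report_ord.fi.index.equals(report_dich.fi.index):
        raise ValueError("the two schemes score different individual sets")
    if anova is None:
        if sex is None:
            raise ValueError("provide either a fitted AnovaResult or a sex series")
        anova = mean_fi_anova(report_ord.fi, report_dich.fi, sex)
    delta_mean = anova.delta_adjusted_mean
    delta_auc_by_sex = {
        sx: abs(report_ord.auc_by_sex[sx].auc - report_dich.auc_by_sex[sx].auc)
        for sx in report_ord.auc_by_sex
        if sx in report_dich.auc_by_sex
    }
    return ComparisonReport(
        ordinal=report_ord,
        dichotomous=report_dich,
        anova=anova,
        n_items=n_items,
        delta_mean_fi=delta_mean,
        delta_mean_deficits=delta_mean * n_items,
        delta_hr_fi=abs(report_ord.cox.hr_fi - report_dich.cox.hr_fi),
        delta_auc=abs(report_ord.auc.auc - report_dich.auc.auc),
        delta_auc_by_sex=delta_auc_by_sex,
    )
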