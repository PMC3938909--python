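"""Synthetic cohorts with the statistical structure a frailty index assumes.

The generator produces graded item responses from a single age-linked latent
liability and death times from a Gompertz hazard driven by the *true* ordinal
frailty index, so every downstream stage (coding, scoring, ANOVA, Cox, ROC)
can be exercised against known generating parameters.

Generating model
----------------
For individual *i* with age ``a_i`` and sex indicator ``f_i`` (1 = female):

* liability  ``L_i = alpha0 + alpha1 * (a_i - age_lo) + sex_effect * f_i + u_i``
  with ``u_i ~ Normal(0, sigma^2)``;
* item *j* (K_j levels, discrimination ``lambda_j``, ordered thresholds
  ``tau_j1 < ... < tau_j,K-1``) responds at level
  ``l_ij = #{k : lambda_j * L_i + e_ij > tau_jk}`` with standard-logistic
  ``e_ij`` — the graded (ordered-logistic) response model;
* ordinal deficit value ``l_ij / (K_j - 1)``; dichotomous value
  ``1{l_ij >= cut_j}`` — both encodings collapse the *same* generated level;
* death time from the Gompertz hazard
  ``h_i(t) = h0 * exp(gamma * t) * exp(beta_fi * 100 * FI_i + beta_age * a_i
  + beta_sex * f_i)`` by inverse-transform sampling, administratively
  censored at the follow-up horizon.  ``FI_i`` is the true ordinal FI over
  all items (before missingness), so ``beta_fi`` is the log hazard ratio per
  0.01 FI.

Cells are then blanked completely at random at ``missing_rate``.  Three
presets (``nshs_like``, ``share_like``, ``yale_like``) encode the item
counts, level compositions, age distributions, sex fractions and follow-up
horizons of three published cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .schema import CodingSchema, LevelMap, VariableCoding

__all__ = [
    "ItemSpec",
    "LiabilityParams",
    "HazardParams",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "schema_for_spec",
    "preset_spec",
    "recovery_experiment",
    "PRESETS",
]

PRESETS = ("nshs_like", "share_like", "yale_like")

#: hazard ratio per 0.01 FI that the presets generate
PRESET_HR_FI = 1.04


@dataclass(frozen=True)
class ItemSpec:
    """One simulated item: a K-level graded response."""

    name: str
    n_levels: int
    discrimination: float
    thresholds: tuple[float, ...]
    dichotomy_cut: int = 1  # level >= cut counts as deficit present

    def __post_init__(self) -> None:
        if not 2 <= self.n_levels <= 5:
            raise ValueError(f"{self.name}: n_levels must be in 2..5")
        if len(self.thresholds) != self.n_levels - 1:
            raise ValueError(f"{self.name}: need {self.n_levels - 1} thresholds")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"{self.name}: thresholds must be strictly increasing")
        if self.discrimination < 0:
            raise ValueError(f"{self.name}: discrimination must be >= 0")
        if not 1 <= self.dichotomy_cut <= self.n_levels - 1:
            raise ValueError(f"{self.name}: dichotomy_cut out of range")


@dataclass(frozen=True)
class LiabilityParams:
    intercept: float = -0.5
    age_slope: float = 0.03  # per year above the lower age bound
    sex_effect: float = 0.3  # added for women
    sd: float = 1.0


@dataclass(frozen=True)
class HazardParams:
    baseline: float = 1e-3       # h0, per year
    gompertz_slope: float = 0.09  # gamma, per year of follow-up
    log_hr_fi: float = math.log(PRESET_HR_FI)  # per 0.01 FI
    log_hr_age: float = math.log(1.08)         # per year of age
    log_hr_sex: float = math.log(0.55)         # women vs men


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical spec + seed
    reproduce an identical cohort."""

    name: str
    n: int
    age_range: tuple[float, float]
    items: tuple[ItemSpec, ...]
    female_fraction: float = 0.5
    age_distribution: str = "uniform"  # or "truncated_normal"
    age_mean: float | None = None
    age_sd: float | None = None
    liability: LiabilityParams = field(default_factory=LiabilityParams)
    hazard: HazardParams = field(default_factory=HazardParams)
    follow_up: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy lo < hi")
        if self.age_distribution not in ("uniform", "truncated_normal"):
            raise ValueError(f"unknown age distribution {self.age_distribution!r}")
        if self.age_distribution == "truncated_normal" and (
            self.age_mean is None or self.age_sd is None
        ):
            raise ValueError("truncated_normal needs age_mean and age_sd")
        if self.follow_up <= 0:
            raise ValueError("follow_up must be positive")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate item names")


@dataclass
class SyntheticCohort:
    """Generated raw responses, survival outcomes, and the generating truth."""

    raw_table: pd.DataFrame   # index 'id'; columns age, sex, item columns
    survival: pd.DataFrame    # index 'id'; columns time, event (1 = died)
    truth: pd.DataFrame       # index 'id'; liability, fi_ordinal/dich (true)
    spec: CohortSpec
    schema: CodingSchema      # coding book matching the generated labels

    @property
    def n(self) -> int:
        return len(self.raw_table)


def _level_labels(k: int) -> list[str]:
    return [f"level_{i}" for i in range(k)]


def schema_for_spec(spec: CohortSpec) -> CodingSchema:
    """Coding book for a simulated cohort's label responses.

    Ordinal values lie on the ``k/(K-1)`` grid; the dichotomous map collapses
    levels at the item's ``dichotomy_cut``.
    """
    variables = []
    for it in spec.items:
        k = it.n_levels
        ordinal = LevelMap(
            entries=tuple(
                (lab, lev / (k - 1)) for lev, lab in enumerate(_level_labels(k))
            )
        )
        dich = LevelMap(
            entries=tuple(
                (lab, float(lev >= it.dichotomy_cut))
                for lev, lab in enumerate(_level_labels(k))
            )
        )
        variables.append(VariableCoding(name=it.name, ordinal=ordinal, dichotomous=dich))
    return CodingSchema(
        study_id=spec.name,
        variables=tuple(variables),
        provenance=f"auto-generated coding book for synthetic cohort {spec.name!r}",
        variant="corrected",
    )


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform":
        return rng.uniform(lo, hi, size=spec.n)
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    return truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=spec.n, random_state=rng
    )


def _gompertz_times(
    eta: np.ndarray, hz: HazardParams, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform sampling from h(t) = h0 * exp(gamma t) * exp(eta)."""
    e = rng.exponential(size=eta.shape[0])
    a = hz.baseline * np.exp(eta)
    if hz.gompertz_slope == 0.0:
        return e / a
    g = hz.gompertz_slope
    return np.log1p(g * e / a) / g


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate one cohort; ``seed`` overrides ``spec.seed`` when given."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    k_items = len(spec.items)
    ids = pd.Index(np.arange(n), name="id")
    if n == 0:
        empty = pd.DataFrame(index=ids)
        return SyntheticCohort(
            raw_table=empty.assign(
                age=pd.Series(dtype=float), sex=pd.Series(dtype=object)
            ),
            survival=empty.assign(
                time=pd.Series(dtype=float), event=pd.Series(dtype=int)
            ),
            truth=empty,
            spec=spec,
            schema=schema_for_spec(spec),
        )

    age = _draw_ages(spec, rng)
    female = rng.random(n) < spec.female_fraction
    lb = spec.liability
    liab = (
        lb.intercept
        + lb.age_slope * (age - spec.age_range[0])
        + lb.sex_effect * female
        + rng.normal(0.0, lb.sd, size=n)
    )

    levels = np.empty((n, k_items), dtype=np.int64)
    for j, it in enumerate(spec.items):
        latent = it.discrimination * liab + rng.logistic(size=n)
        levels[:, j] = (latent[:, None] > np.asarray(it.thresholds)).sum(axis=1)

    denom = np.array([it.n_levels - 1 for it in spec.items], dtype=float)
    cuts = np.array([it.dichotomy_cut for it in spec.items])
    ord_vals = levels / denom
    dich_vals = (levels >= cuts).astype(float)
    fi_ord = ord_vals.mean(axis=1)
    fi_dich = dich_vals.mean(axis=1)

    hz = spec.hazard
    eta = (
        hz.log_hr_fi * (100.0 * fi_ord)
        + hz.log_hr_age * age
        + hz.log_hr_sex * female
    )
    t_death = _gompertz_times(eta, hz, rng)
    event = t_death <= spec.follow_up
    time = np.minimum(t_death, spec.follow_up)

    missing = (
        rng.random((n, k_items)) < spec.missing_rate
        if spec.missing_rate > 0
        else np.zeros((n, k_items), dtype=bool)
    )

    raw = pd.DataFrame(index=ids)
    raw["age"] = age
    raw["sex"] = np.where(female, "female", "male")
    for j, it in enumerate(spec.items):
        labels = np.array(_level_labels(it.n_levels), dtype=object)
        col = labels[levels[:, j]]
        col[missing[:, j]] = None
        raw[it.name] = col

    survival = pd.DataFrame(
        {"time": time, "event": event.astype(int)}, index=ids
    )
    truth = pd.DataFrame(
        {
            "liability": liab,
            "fi_ordinal_true": fi_ord,
            "fi_dichotomous_true": fi_dich,
            "age": age,
            "female": female.astype(int),
        },
        index=ids,
    )
    return SyntheticCohort(
        raw_table=raw,
        survival=survival,
        truth=truth,
        spec=spec,
        schema=schema_for_spec(spec),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _make_items(
    composition: dict[int, int], rng: np.random.Generator
) -> tuple[ItemSpec, ...]:
    """Build an item battery with a given {n_levels: count} composition.

    First thresholds are spread over [0.5, 3.5] (deficit prevalences from
    common to rare); higher thresholds follow at gaps of 0.6-1.2 logits.
    Polytomous items dichotomize at the middle level.
    """
    items = []
    idx = 0
    for k in sorted(composition):
        for _ in range(composition[k]):
            idx += 1
            tau1 = rng.uniform(0.5, 3.5)
            gaps = rng.uniform(0.6, 1.2, size=k - 2)
            thresholds = tuple(tau1 + np.concatenate([[0.0], np.cumsum(gaps)]))
            items.append(
                ItemSpec(
                    name=f"item_{idx:03d}",
                    n_levels=k,
                    discrimination=1.0,
                    thresholds=thresholds,
                    dichotomy_cut=max(1, (k - 1) // 2 + (k == 2)),
                )
            )
    return tuple(items)


_PRESET_DEFS = {
    # composition, ages (lo, hi, mean, sd), %female, follow-up, baseline h0
    "nshs_like": dict(
        composition={2: 19, 3: 2, 4: 1, 5: 1},
        age=(18.0, 99.0, 48.1, 19.8),
        female_fraction=0.501,
        follow_up=10.0,
        item_seed=101,
        hazard=HazardParams(
            baseline=1.2e-5,
            gompertz_slope=0.09,
            log_hr_fi=math.log(PRESET_HR_FI),
            log_hr_age=math.log(1.10),
            log_hr_sex=math.log(0.52),
        ),
        liability=LiabilityParams(intercept=-1.2, age_slope=0.035, sex_effect=0.25),
        missing_rate=0.02,
    ),
    "share_like": dict(
        composition={2: 60, 3: 1, 4: 2, 5: 7},
        age=(50.0, 99.0, 64.2, 10.5),
        female_fraction=0.56,
        follow_up=5.0,
        item_seed=102,
        hazard=HazardParams(
            baseline=6.1e-5,
            gompertz_slope=0.09,
            log_hr_fi=math.log(PRESET_HR_FI),
            log_hr_age=math.log(1.08),
            log_hr_sex=math.log(0.50),
        ),
        liability=LiabilityParams(intercept=-0.6, age_slope=0.03, sex_effect=0.3),
        missing_rate=0.02,
    ),
    "yale_like": dict(
        composition={2: 12, 3: 14, 4: 1, 5: 6},
        age=(70.0, 99.0, 78.4, 5.3),
        female_fraction=0.646,
        follow_up=12.9,
        item_seed=103,
        hazard=HazardParams(
            baseline=8.7e-5,
            gompertz_slope=0.09,
            log_hr_fi=math.log(PRESET_HR_FI),
            log_hr_age=math.log(1.08),
            log_hr_sex=math.log(0.65),
        ),
        liability=LiabilityParams(intercept=-0.3, age_slope=0.04, sex_effect=0.3),
        missing_rate=0.02,
    ),
}


def preset_spec(
    name: str,
    n: int = 2000,
    seed: int = 0,
    missing_rate: float | None = None,
) -> CohortSpec:
    """A named preset cohort spec (``nshs_like``, ``share_like``,
    ``yale_like``) emulating the corresponding study's structure.

    The item battery (level composition and thresholds) is a fixed part of
    each preset — it is drawn from a preset-specific internal seed, not from
    ``seed``, so the cohort seed varies individuals only.
    """
    if name not in _PRESET_DEFS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    d = _PRESET_DEFS[name]
    items = _make_items(d["composition"], np.random.default_rng(d["item_seed"]))
    lo, hi, mean, sd = d["age"]
    return CohortSpec(
        name=name,
        n=n,
        age_range=(lo, hi),
        age_distribution="truncated_normal",
        age_mean=mean,
        age_sd=sd,
        items=items,
        female_fraction=d["female_fraction"],
        liability=d["liability"],
        hazard=d["hazard"],
        follow_up=d["follow_up"],
        missing_rate=d["missing_rate"] if missing_rate is None else missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


def recovery_experiment(
    spec: CohortSpec,
    replicates: int,
    seed: int | None = None,
    missing_threshold: float = 0.20,
    include_null_covariate: bool = False,
) -> pd.DataFrame:
    """Repeatedly generate, score and Cox-fit; report recovery per replicate.

    Each replicate generates a cohort from ``spec``, encodes and scores both
    frailty indices, and fits the mortality Cox model (FI per 0.01, age,
    female, optionally an extra standard-normal covariate independent of
    death) on the *ordinal* FI.  The returned frame has one row per replicate
    and parameter with the estimate, CI, generating value and a coverage
    flag; replicates with zero events are recorded as failed rows rather than
    silently dropped.  Summarize with ``df.groupby('parameter')``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .engine import compute_fi, encode_responses
    from .stats import cox_mortality

    base = spec.seed if seed is None else seed
    master = np.random.default_rng(base)
    truth_by_param = {
        "fi_per_0.01": spec.hazard.log_hr_fi,
        "age": spec.hazard.log_hr_age,
        "female": spec.hazard.log_hr_sex,
        "null": 0.0,
    }
    rows = []
    for r in range(replicates):
        rep_seed = int(master.integers(0, 2**31 - 1))
        cohort = generate_cohort(replace(spec, seed=rep_seed))
        fi_ord = compute_fi(
            encode_responses(cohort.raw_table, cohort.schema, "ordinal"),
            missing_threshold,
        )
        fi_dich = compute_fi(
            encode_responses(cohort.raw_table, cohort.schema, "dichotomous"),
            missing_threshold,
        )
        keep = ~(fi_ord["excluded"] | fi_dich["excluded"])
        surv = cohort.survival.loc[keep].copy()
        surv["age"] = cohort.raw_table.loc[keep, "age"]
        surv["sex"] = cohort.raw_table.loc[keep, "sex"]
        extra = None
        if include_null_covariate:
            extra = pd.Series(
                np.random.default_rng(rep_seed + 1).normal(size=keep.sum()),
                index=surv.index,
                name="null",
            )
        if surv["event"].sum() == 0:
            for param in truth_by_param:
                rows.append(
                    dict(
                        replicate=r, seed=rep_seed, parameter=param, failed=True,
                        n=int(keep.sum()), n_events=0, coef=np.nan, hr=np.nan,
                        ci_low=np.nan, ci_high=np.nan, truth_coef=truth_by_param[param],
                        covered=np.nan,
                    )
                )
            continue
        fit = cox_mortality(
            fi_ord.loc[keep, "fi"], surv, extra_covariates=extra
        )
        for param, truth in truth_by_param.items():
            if param == "null" and not include_null_covariate:
                continue
            est = fit.summary.loc[param]
            truth_hr = math.exp(truth)
            rows.append(
                dict(
                    replicate=r,
                    seed=rep_seed,
                    parameter=param,
                    failed=False,
                    n=int(keep.sum()),
                    n_events=int(surv["event"].sum()),
                    coef=est["coef"],
                    hr=est["hr"],
                    ci_low=est["hr_ci_low"],
                    ci_high=est["hr_ci_high"],
                    truth_coef=truth,
                    covered=bool(est["hr_ci_low"] <= truth_hr <= est["hr_ci_high"]),
                )
            )
    return pd.DataFrame(rows)
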