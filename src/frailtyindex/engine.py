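"""Encoding raw responses into deficits and computing frailty-index scores.

The frailty index of individual *i* is

    FI_i = (sum of coded deficit values over non-missing items) / m_i

where ``m_i`` is the individual's number of non-missing items.  Individuals
missing more than ``missing_threshold`` (default 20%) of the index's items are
excluded (the comparison is strict, so exactly-at-threshold individuals are
retained).  Missing items never contribute to the numerator; the shrinking
denominator is the standard deficit-accumulation mechanism, so no imputation
is performed.

:func:`screen_variables` implements the standard item-selection criteria as an
advisory report: items should carry little missing data (<=5%), should not
saturate with age (present in >80% of people aged 80+), and should be
age-related.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schema import CodingSchema, LevelMap, NumericBinMap, SchemaError

__all__ = [
    "DeficitMatrix",
    "encode_responses",
    "compute_fi",
    "screen_variables",
]

_SEX_ALIASES = {
    "male": "male", "m": "male", "man": "male", "men": "male",
    "female": "female", "f": "female", "woman": "female", "women": "female",
    "0": "male", "1": "female",
}


def normalize_sex(values: pd.Series) -> pd.Series:
    """Map a raw sex column onto {'male', 'female'} (NaN preserved)."""
    s = values.astype("string").str.strip().str.lower().map(_SEX_ALIASES)
    bad = values.notna() & s.isna()
    if bad.any():
        raise ValueError(
            f"unrecognized sex values: {sorted(values[bad].unique().tolist())}"
        )
    return s


@dataclass
class DeficitMatrix:
    """Individuals x items grid of coded deficit values.

    ``values`` is a float DataFrame in [0, 1] with NaN for missing; its index
    identifies individuals and its columns are the schema's item names.
    ``unmapped_by_item`` tallies raw responses that matched no coding rule
    (they are coded missing, but reported so silent data loss is visible).
    """

    values: pd.DataFrame
    scheme: str
    unmapped_by_item: dict[str, int] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_unmapped(self) -> int:
        return int(sum(self.unmapped_by_item.values()))


def _encode_level_column(col: pd.Series, m: LevelMap) -> tuple[pd.Series, int]:
    s = col.astype("string").str.strip()
    mapping = {lab: val for lab, val in m.entries}
    coded = s.map(mapping)
    known_missing = s.isna() | (s == "") | s.isin(m.missing_labels)
    unmapped = coded.isna() & ~known_missing
    return coded.astype(float), int(unmapped.sum())


def _encode_bins(x: np.ndarray, bins) -> np.ndarray:
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    for b in bins:
        lo = -np.inf if b.lo is None else b.lo
        hi = np.inf if b.hi is None else b.hi
        above = (x > lo) if b.lo_open else (x >= lo)
        below = (x < hi) if b.hi_open else (x <= hi)
        sel = ok & above & below
        out[sel] = b.value
    return out


def _encode_numeric_column(
    col: pd.Series, m: NumericBinMap, sex: pd.Series | None
) -> tuple[pd.Series, int]:
    if col.dtype == object or pd.api.types.is_string_dtype(col):
        s = col.astype("string").str.strip()
        s = s.mask((s == "") | s.isin(m.missing_labels))
        numeric = pd.to_numeric(s, errors="coerce")
        unmapped = int((numeric.isna() & s.notna()).sum())
    else:
        numeric = pd.to_numeric(col, errors="coerce")
        unmapped = 0
    x = numeric.to_numpy(dtype=float)
    if not m.sex_specific:
        coded = _encode_bins(x, m.bins)
    else:
        coded = np.full(x.shape, np.nan)
        for sx in ("male", "female"):
            sel = (sex == sx).to_numpy()
            coded[sel] = _encode_bins(x[sel], m.by_sex[sx])
        # measurements of individuals with unknown sex cannot be coded
        unmapped += int((sex.isna() & ~np.isnan(x)).sum())
    return pd.Series(coded, index=col.index, dtype=float), unmapped


def encode_responses(
    raw_table: pd.DataFrame,
    schema: CodingSchema,
    scheme: str,
    sex_column: str = "sex",
) -> DeficitMatrix:
    """Code a raw cohort table into a :class:`DeficitMatrix`.

    Parameters
    ----------
    raw_table
        One row per individual; one column per schema item (categorical items
        as labels, numeric-bin items as measurements), plus a sex column if
        any coding map is sex-specific.
    schema, scheme
        The coding book and the regime (``"ordinal"`` or ``"dichotomous"``).

    Unrecognized labels are coded missing and tallied per item in
    ``unmapped_by_item``; items named in the schema but absent from the table
    raise immediately.
    """
    if scheme not in ("ordinal", "dichotomous"):
        raise ValueError(f"scheme must be 'ordinal' or 'dichotomous', got {scheme!r}")
    missing_items = [n for n in schema.item_names if n not in raw_table.columns]
    if missing_items:
        raise KeyError(
            f"raw table lacks {len(missing_items)} schema item(s): {missing_items}"
        )
    sex = None
    if schema.sex_specific:
        if sex_column not in raw_table.columns:
            raise SchemaError(
                f"schema {schema.study_id!r} has sex-specific codings but the "
                f"table has no {sex_column!r} column"
            )
        sex = normalize_sex(raw_table[sex_column])

    coded_cols: dict[str, pd.Series] = {}
    unmapped: dict[str, int] = {}
    for v in schema.variables:
        m = getattr(v, scheme)
        if isinstance(m, LevelMap):
            coded, n_bad = _encode_level_column(raw_table[v.name], m)
        else:
            coded, n_bad = _encode_numeric_column(raw_table[v.name], m, sex)
        coded_cols[v.name] = coded
        if n_bad:
            unmapped[v.name] = n_bad
    values = pd.DataFrame(coded_cols, index=raw_table.index)[list(schema.item_names)]
    return DeficitMatrix(values=values, scheme=scheme, unmapped_by_item=unmapped)


def compute_fi(
    matrix: DeficitMatrix | pd.DataFrame,
    missing_threshold: float = 0.20,
) -> pd.DataFrame:
    """Score a deficit matrix into per-individual frailty indices.

    Returns a DataFrame indexed like the matrix with columns ``fi`` (NaN when
    excluded), ``n_nonmissing``, ``n_items``, ``missing_fraction``,
    ``excluded`` and ``scheme``.  An individual is excluded when the missing
    fraction strictly exceeds ``missing_threshold`` (default 0.20), or when
    no item at all is non-missing.  The missing-fraction denominator is the
    schema's full item count.
    """
    if isinstance(matrix, DeficitMatrix):
        values, scheme = matrix.values, matrix.scheme
    else:
        values, scheme = matrix, ""
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty deficit matrix")
    if not 0.0 <= missing_threshold < 1.0:
        raise ValueError("missing_threshold must be in [0, 1)")
    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
        raise ValueError("deficit values outside [0, 1]")
    n_items = arr.shape[1]
    n_nonmissing = np.sum(~np.isnan(arr), axis=1)
    missing_fraction = 1.0 - n_nonmissing / n_items
    excluded = (missing_fraction > missing_threshold) | (n_nonmissing == 0)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(arr, axis=1) / np.where(n_nonmissing > 0, n_nonmissing, np.nan)
    fi[excluded] = np.nan
    out = pd.DataFrame(
        {
            "fi": fi,
            "n_nonmissing": n_nonmissing.astype(int),
            "n_items": n_items,
            "missing_fraction": missing_fraction,
            "excluded": excluded,
        },
        index=values.index,
    )
    if scheme:
        out["scheme"] = scheme
    return out


def screen_variables(
    raw_table: pd.DataFrame,
    schema: CodingSchema,
    age_column: str = "age",
    sex_column: str = "sex",
    missing_threshold: float = 0.05,
    saturation_threshold: float = 0.80,
    saturation_age: float = 80.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Advisory item-screening report (one row per schema item).

    For each item: the missing fraction (<= 5% proposed), prevalence of the
    deficit among individuals aged ``saturation_age``+ (saturation when
    > 80%), and a Spearman rank test of the coded value against age
    (``not_age_related`` when p >= alpha).  Prevalence and age association are
    computed on the dichotomous coding (presence/absence).  The ``saturated``
    column is nullable: when nobody reaches ``saturation_age`` it is <NA>
    ("not assessable"), never a silent pass.  Screening never drops variables;
    it only reports.
    """
    if age_column not in raw_table.columns:
        raise KeyError(f"no {age_column!r} column in table")
    age = pd.to_numeric(raw_table[age_column], errors="coerce")
    dich = encode_responses(raw_table, schema, "dichotomous", sex_column)
    old = (age >= saturation_age).to_numpy()
    rows = []
    for item in dich.item_names:
        coded = dich.values[item]
        miss_frac = float(coded.isna().mean())
        sat_prev = np.nan
        if old.any():
            sub = coded[old].dropna()
            sat_prev = float((sub == 1.0).mean()) if len(sub) else np.nan
        ok = coded.notna() & age.notna()
        rho, pval = np.nan, np.nan
        if ok.sum() >= 3 and coded[ok].nunique() > 1 and age[ok].nunique() > 1:
            rho, pval = sps.spearmanr(coded[ok], age[ok])
        rows.append(
            {
                "item": item,
                "missing_fraction": miss_frac,
                "saturation_prevalence": sat_prev,
                "age_spearman_rho": rho,
                "age_spearman_p": pval,
                "too_missing": miss_frac > missing_threshold,
                "saturated": (
                    pd.NA if np.isnan(sat_prev) else bool(sat_prev > saturation_threshold)
                ),
                # an inestimable correlation (constant item) is not evidence
                # of age-relatedness, so it flags as well
                "not_age_related": not (pval < alpha),
            }
        )
    report = pd.DataFrame(rows).set_index("item")
    report["saturated"] = report["saturated"].astype("boolean")
    return report
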