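"""Per-variable deficit coding rules for frailty indices.

A deficit-accumulation frailty index maps each health variable onto the unit
interval (0 = deficit absent, 1 = fully expressed).  Two coding regimes are
supported for every variable:

* **ordinal** — graded severity (e.g. 0, 0.5, 1 for a three-level response);
* **dichotomous** — presence/absence only (0 or 1).

Categorical responses are coded through a :class:`LevelMap` (response label ->
value); continuous or count measurements (blood pressure, gait time, MMSE,
peak flow ...) through a :class:`NumericBinMap`, optionally sex-specific.

Three study schemas are packaged as JSON fixtures (``nshs``, ``share``,
``yale_pep``), each in two variants: ``as_printed`` transcribes the published
codings verbatim, including two internally inconsistent rows; ``corrected``
repairs those two rows (see :func:`validate_schema`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import yaml

__all__ = [
    "SchemaError",
    "Diagnostic",
    "LevelMap",
    "Bin",
    "NumericBinMap",
    "VariableCoding",
    "CodingSchema",
    "load_schema",
    "write_schema",
    "validate_schema",
    "schema_summary",
    "load_packaged_schema",
    "packaged_schema_path",
    "PACKAGED_STUDIES",
    "SCHEMA_VARIANTS",
]

PACKAGED_STUDIES = ("nshs", "share", "yale_pep")
SCHEMA_VARIANTS = ("as_printed", "corrected")

#: directions a numeric bin map can declare: "increasing" means a larger
#: measurement is worse (e.g. gait time), "decreasing" means larger is better
#: (e.g. peak flow), "range" means there is a healthy mid-range with deficit
#: on both tails (e.g. blood pressure, BMI).
_DIRECTIONS = ("increasing", "decreasing", "range")


class SchemaError(ValueError):
    """A coding schema failed to parse or violated a structural invariant."""


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    variable: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.variable}: {self.message}"


# ---------------------------------------------------------------------------
# coding maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelMap:
    """Ordered response-label -> deficit-value map for a categorical item.

    The declared entry order is the severity order of the response scale.
    Labels in ``missing_labels`` are treated as missing rather than unmapped.
    """

    entries: tuple[tuple[str, float], ...]
    missing_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise SchemaError("a level map needs at least 2 entries")
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise SchemaError("duplicate response labels in level map")
        for lab, val in self.entries:
            if not (0.0 <= val <= 1.0):
                raise SchemaError(
                    f"deficit value {val!r} for label {lab!r} outside [0, 1]"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(val for _, val in self.entries)

    def encode(self, response: object) -> Union[float, None, type(Ellipsis)]:
        """Map one raw response.

        Returns the deficit value, ``None`` for missing, or ``Ellipsis`` for
        an unmapped (unrecognized) label.
        """
        if response is None or (isinstance(response, float) and math.isnan(response)):
            return None
        label = str(response).strip()
        if label in self.missing_labels or label == "":
            return None
        for lab, val in self.entries:
            if lab == label:
                return val
        return Ellipsis


@dataclass(frozen=True)
class Bin:
    """One interval of a numeric coding; ``lo``/``hi`` of ``None`` mean ±inf.

    Membership defaults to closed-left / open-right, ``lo <= x < hi``;
    the flags override either side so printed <=/< cutoffs are kept exact.
    """

    lo: float | None
    hi: float | None
    value: float
    lo_open: bool = False
    hi_open: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise SchemaError(f"bin value {self.value!r} outside [0, 1]")
        lo = -math.inf if self.lo is None else self.lo
        hi = math.inf if self.hi is None else self.hi
        if not lo < hi:
            raise SchemaError(f"empty bin: lo={self.lo!r} hi={self.hi!r}")

    def contains(self, x: float) -> bool:
        lo = -math.inf if self.lo is None else self.lo
        hi = math.inf if self.hi is None else self.hi
        above = x > lo if self.lo_open else x >= lo
        below = x < hi if self.hi_open else x <= hi
        return above and below


def _check_bins(bins: tuple[Bin, ...]) -> None:
    if len(bins) < 2:
        raise SchemaError("a numeric bin map needs at least 2 bins")
    lo0 = -math.inf if bins[0].lo is None else bins[0].lo
    if lo0 != -math.inf:
        raise SchemaError("first bin must be unbounded below")
    if bins[-1].hi is not None:
        raise SchemaError("last bin must be unbounded above")
    for prev, nxt in zip(bins, bins[1:]):
        if prev.hi is None or nxt.lo is None or prev.hi != nxt.lo:
            raise SchemaError(
                f"bins not contiguous at {prev.hi!r} / {nxt.lo!r}"
            )
        # the shared boundary must belong to exactly one side
        if prev.hi_open == nxt.lo_open:
            raise SchemaError(
                f"boundary {prev.hi!r} belongs to "
                f"{'neither' if prev.hi_open else 'both'} adjacent bins"
            )


@dataclass(frozen=True)
class NumericBinMap:
    """Interval -> deficit-value map for a numeric measurement.

    Either ``bins`` (shared by everyone) or ``by_sex`` (separate bin lists for
    ``"male"`` and ``"female"``) is set.  ``direction`` declares the clinical
    orientation of the measurement and drives monotonicity validation.
    """

    bins: tuple[Bin, ...] | None = None
    by_sex: Mapping[str, tuple[Bin, ...]] | None = None
    direction: str = "increasing"
    missing_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.bins is None) == (self.by_sex is None):
            raise SchemaError("exactly one of bins/by_sex must be given")
        if self.direction not in _DIRECTIONS:
            raise SchemaError(f"unknown direction {self.direction!r}")
        if self.bins is not None:
            _check_bins(self.bins)
        else:
            if set(self.by_sex) != {"male", "female"}:
                raise SchemaError("by_sex must provide 'male' and 'female'")
            for b in self.by_sex.values():
                _check_bins(b)

    @property
    def sex_specific(self) -> bool:
        return self.by_sex is not None

    def bins_for(self, sex: str | None = None) -> tuple[Bin, ...]:
        if self.bins is not None:
            return self.bins
        if sex not in ("male", "female"):
            raise SchemaError(
                f"sex-specific map requires sex 'male' or 'female', got {sex!r}"
            )
        return self.by_sex[sex]

    def encode(self, response: object, sex: str | None = None):
        """Map one raw measurement; semantics as :meth:`LevelMap.encode`."""
        if response is None:
            return None
        if isinstance(response, str):
            label = response.strip()
            if label == "" or label in self.missing_labels:
                return None
            try:
                response = float(label)
            except ValueError:
                return Ellipsis
        try:
            x = float(response)
        except (TypeError, ValueError):
            return Ellipsis
        if math.isnan(x):
            return None
        for b in self.bins_for(sex):
            if b.contains(x):
                return b.value
        return Ellipsis  # unreachable for contiguous unbounded bins

    @property
    def values(self) -> tuple[float, ...]:
        """Bin values in ascending measurement order (male branch if sexed)."""
        return tuple(b.value for b in (self.bins or self.by_sex["male"]))


CodingMap = Union[LevelMap, NumericBinMap]


# ---------------------------------------------------------------------------
# variables and schemas
# ---------------------------------------------------------------------------


def _n_grades(m: CodingMap) -> int:
    """Number of severity grades of a coding map.

    For level maps and monotone bin maps every declared level/bin is its own
    grade.  For 'range' maps the two tails of the measurement reach the same
    deficit severity, so grades are the distinct coded values (e.g. systolic
    blood pressure 0.5/0/0.5/1 is a 3-level coding).
    """
    if isinstance(m, LevelMap):
        return len(m.entries)
    if m.direction == "range":
        return len(set(m.values))
    return len(m.values)


@dataclass(frozen=True)
class VariableCoding:
    """One variable with its ordinal and dichotomous coding maps."""

    name: str
    ordinal: CodingMap
    dichotomous: CodingMap

    def __post_init__(self) -> None:
        vals = set()
        if isinstance(self.dichotomous, LevelMap):
            vals = set(self.dichotomous.values)
        else:
            for bins in (
                (self.dichotomous.bins,)
                if self.dichotomous.bins is not None
                else tuple(self.dichotomous.by_sex.values())
            ):
                vals |= {b.value for b in bins}
        if vals != {0.0, 1.0}:
            raise SchemaError(
                f"variable {self.name!r}: dichotomous values must be exactly "
                f"{{0, 1}}, got {sorted(vals)}"
            )

    @property
    def n_levels_ordinal(self) -> int:
        return _n_grades(self.ordinal)

    @property
    def is_numeric(self) -> bool:
        return isinstance(self.ordinal, NumericBinMap)

    @property
    def sex_specific(self) -> bool:
        return any(
            isinstance(m, NumericBinMap) and m.sex_specific
            for m in (self.ordinal, self.dichotomous)
        )


@dataclass(frozen=True)
class CodingSchema:
    """The full coding book for one study: every variable, both regimes."""

    study_id: str
    variables: tuple[VariableCoding, ...]
    provenance: str = ""
    variant: str = "corrected"
    missing_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.variables:
            raise SchemaError("empty schema")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dup}")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableCoding]:
        return iter(self.variables)

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> VariableCoding:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def sex_specific(self) -> bool:
        return any(v.sex_specific for v in self.variables)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def _bin_from_dict(d: Mapping, where: str) -> Bin:
    try:
        return Bin(
            lo=d.get("lo"),
            hi=d.get("hi"),
            value=float(d["value"]),
            lo_open=bool(d.get("lo_open", False)),
            hi_open=bool(d.get("hi_open", True)),
        )
    except KeyError as e:
        raise SchemaError(f"{where}: bin missing field {e}") from e


def _map_from_dict(d: Mapping, where: str, missing: frozenset[str]) -> CodingMap:
    if not isinstance(d, Mapping):
        raise SchemaError(f"{where}: coding map must be a mapping")
    extra = frozenset(str(x) for x in d.get("missing_labels", ())) | missing
    if "levels" in d:
        entries = []
        for e in d["levels"]:
            try:
                entries.append((str(e["label"]), float(e["value"])))
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"{where}: bad level entry {e!r}") from exc
        return LevelMap(entries=tuple(entries), missing_labels=extra)
    if "bins" in d or "by_sex" in d:
        direction = str(d.get("direction", "increasing"))
        if "by_sex" in d:
            by_sex = {
                str(sex): tuple(_bin_from_dict(b, where) for b in bins["bins"])
                for sex, bins in d["by_sex"].items()
            }
            return NumericBinMap(
                by_sex=by_sex, direction=direction, missing_labels=extra
            )
        bins = tuple(_bin_from_dict(b, where) for b in d["bins"])
        return NumericBinMap(bins=bins, direction=direction, missing_labels=extra)
    raise SchemaError(f"{where}: coding map needs 'levels', 'bins' or 'by_sex'")


def schema_from_dict(doc: Mapping) -> CodingSchema:
    """Build a :class:`CodingSchema` from a parsed JSON/YAML document."""
    if not isinstance(doc, Mapping):
        raise SchemaError("schema document must be a mapping")
    raw_vars = doc.get("variables")
    if not raw_vars:
        raise SchemaError("empty schema")
    missing = frozenset(str(x) for x in doc.get("missing_labels", ()))
    variables = []
    for i, rv in enumerate(raw_vars):
        name = str(rv.get("name", f"<variable {i}>"))
        where = f"variable {name!r}"
        try:
            ordinal = _map_from_dict(rv["ordinal"], where + " (ordinal)", missing)
            dich = _map_from_dict(
                rv["dichotomous"], where + " (dichotomous)", missing
            )
            variables.append(
                VariableCoding(name=name, ordinal=ordinal, dichotomous=dich)
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing field {e}") from e
        except SchemaError as e:
            raise SchemaError(f"{where}: {e}") from e
    return CodingSchema(
        study_id=str(doc.get("study_id", "unknown")),
        variables=tuple(variables),
        provenance=str(doc.get("provenance", "")),
        variant=str(doc.get("variant", "corrected")),
        missing_labels=missing,
    )


def _bin_to_dict(b: Bin) -> dict:
    d: dict = {"lo": b.lo, "hi": b.hi, "value": b.value}
    if b.lo_open:
        d["lo_open"] = True
    if not b.hi_open:
        d["hi_open"] = False
    return d


def _map_to_dict(m: CodingMap, schema_missing: frozenset[str]) -> dict:
    extra = sorted(m.missing_labels - schema_missing)
    d: dict = {}
    if isinstance(m, LevelMap):
        d["levels"] = [{"label": lab, "value": val} for lab, val in m.entries]
    else:
        d["direction"] = m.direction
        if m.bins is not None:
            d["bins"] = [_bin_to_dict(b) for b in m.bins]
        else:
            d["by_sex"] = {
                sex: {"bins": [_bin_to_dict(b) for b in bins]}
                for sex, bins in m.by_sex.items()
            }
    if extra:
        d["missing_labels"] = extra
    return d


def schema_to_dict(schema: CodingSchema) -> dict:
    return {
        "study_id": schema.study_id,
        "variant": schema.variant,
        "provenance": schema.provenance,
        "missing_labels": sorted(schema.missing_labels),
        "variables": [
            {
                "name": v.name,
                "ordinal": _map_to_dict(v.ordinal, schema.missing_labels),
                "dichotomous": _map_to_dict(v.dichotomous, schema.missing_labels),
            }
            for v in schema.variables
        ],
    }


def load_schema(path: str | Path) -> CodingSchema:
    """Load and structurally validate a coding schema from JSON or YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise SchemaError(f"{path.name}: cannot parse: {e}") from e
    try:
        return schema_from_dict(doc)
    except SchemaError as e:
        raise SchemaError(f"{path.name}: {e}") from e


def write_schema(schema: CodingSchema, path: str | Path) -> None:
    """Serialize a schema; round-trips through :func:`load_schema`."""
    path = Path(path)
    doc = schema_to_dict(schema)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))
    else:
        path.write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# validation and summaries
# ---------------------------------------------------------------------------


def _monotone_ok(values: Iterable[float], direction: str) -> bool:
    vals = list(values)
    if direction == "increasing":
        return all(a <= b for a, b in zip(vals, vals[1:]))
    if direction == "decreasing":
        return all(a >= b for a, b in zip(vals, vals[1:]))
    # range: severity may fall then rise (healthy mid-range), never re-fall
    k = 0
    n = len(vals)
    while k + 1 < n and vals[k] >= vals[k + 1]:
        k += 1
    return all(a <= b for a, b in zip(vals[k:], vals[k + 1 :]))


def _check_map_monotone(
    name: str, kind: str, m: CodingMap, out: list[Diagnostic]
) -> None:
    if isinstance(m, LevelMap):
        if not _monotone_ok(m.values, "increasing"):
            out.append(
                Diagnostic(
                    "warning",
                    name,
                    f"{kind} values {list(m.values)} are not non-decreasing "
                    "along the declared severity order",
                )
            )
        return
    branches = (
        {"": m.bins} if m.bins is not None else dict(m.by_sex)
    )
    for sex, bins in branches.items():
        vals = [b.value for b in bins]
        if not _monotone_ok(vals, m.direction):
            tag = f" ({sex})" if sex else ""
            out.append(
                Diagnostic(
                    "warning",
                    name,
                    f"{kind} bin values {vals}{tag} are inconsistent with the "
                    f"declared '{m.direction}' direction",
                )
            )


def validate_schema(schema: CodingSchema) -> list[Diagnostic]:
    """Run content-level checks beyond the structural invariants.

    Structural problems (values outside [0,1], duplicate labels, gappy bins)
    already raise at construction; this reports the softer issues as
    diagnostics.  Non-monotone severity sequences are warnings, not errors:
    two published codings violate monotonicity as printed (the SHARE delayed
    recall scale and the women's shoulder-strength top bin) and the
    ``as_printed`` fixtures transcribe them faithfully.
    """
    out: list[Diagnostic] = []
    for v in schema.variables:
        _check_map_monotone(v.name, "ordinal", v.ordinal, out)
        _check_map_monotone(v.name, "dichotomous", v.dichotomous, out)
        if isinstance(v.ordinal, LevelMap) and isinstance(v.dichotomous, LevelMap):
            missing = set(v.ordinal.labels) - set(v.dichotomous.labels)
            if missing:
                out.append(
                    Diagnostic(
                        "error",
                        v.name,
                        f"ordinal labels {sorted(missing)} have no dichotomous "
                        "coding",
                    )
                )
    return out


def schema_summary(schema: CodingSchema) -> dict:
    """Level-count composition: {n_levels: n_variables}, plus ``'total'``."""
    counts: dict[int, int] = {}
    for v in schema.variables:
        k = v.n_levels_ordinal
        counts[k] = counts.get(k, 0) + 1
    summary = dict(sorted(counts.items()))
    summary["total"] = len(schema)
    return summary


def packaged_schema_path(study: str, variant: str = "corrected") -> Path:
    """Filesystem path of a packaged study schema fixture."""
    if study not in PACKAGED_STUDIES:
        raise ValueError(f"unknown study {study!r}; choose from {PACKAGED_STUDIES}")
    if variant not in SCHEMA_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {SCHEMA_VARIANTS}")
    ref = resources.files("frailtyindex") / "schemas" / f"{study}.{variant}.json"
    return Path(str(ref))


def load_packaged_schema(study: str, variant: str = "corrected") -> CodingSchema:
    """Load one of the packaged study schemas (nshs, share, yale_pep)."""
    return load_schema(packaged_schema_path(study, variant))
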