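"""End-to-end comparison model: cohort + coding book -> fitted comparison.

:class:`FrailtyComparison` is built from a raw cohort table, a survival
table and a :class:`~frailtyindex.schema.CodingSchema`; ``fit()`` encodes the
cohort under both coding regimes, scores both frailty indices, harmonizes
exclusions (an individual over the missingness threshold under *either*
regime is dropped from both, so all paired contrasts are computed on a
common set), and runs the full validation battery.  The returned
:class:`FrailtyComparisonResults` carries the per-individual scores, the
paired :class:`~frailtyindex.stats.ComparisonReport`, a run manifest with
reconciled row counts, and writes/prints Table-style summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import compute_fi, encode_responses, normalize_sex, screen_variables
from .schema import CodingSchema, validate_schema
from .stats import (
    ComparisonReport,
    build_scheme_report,
    compare_indices,
    mean_fi_anova,
    roc_curve_points,
)

__all__ = ["FrailtyComparison", "FrailtyComparisonResults"]


def _frame_checksum(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FrailtyComparisonResults:
    """Fitted ordinal-vs-dichotomous comparison for one cohort."""

    model: "FrailtyComparison" = field(repr=False)
    fi_table: pd.DataFrame
    report: ComparisonReport
    schema_diagnostics: list
    manifest: dict

    # -- convenience accessors -------------------------------------------
    @property
    def delta_auc(self) -> float:
        return self.report.delta_auc

    @property
    def delta_mean_fi(self) -> float:
        return self.report.delta_mean_fi

    @property
    def delta_hr_fi(self) -> float:
        return self.report.delta_hr_fi

    def summary(self) -> str:
        """Human-readable report: scheme x sex means and AUCs, Cox HRs,
        and the paired deltas."""
        rep = self.report
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append(
            f"Frailty index comparison — cohort {self.manifest['study_id']!r}, "
            f"{rep.n_items} items"
        )
        lines.append("=" * w)
        m = self.manifest
        lines.append(
            f"individuals read {m['n_read']}, scored {m['n_modeled']}, "
            f"excluded (> {m['missing_threshold']:.0%} items missing under "
            f"either coding) {m['n_excluded']}; deaths {m['n_events']}"
        )
        lines.append("")
        lines.append("Mean FI (SD) and ROC area (95% CI) by scheme and sex")
        lines.append("-" * w)
        hdr = f"{'scheme':<13}{'sex':<9}{'mean FI (SD)':<18}{'AUC (95% CI)':<24}"
        lines.append(hdr)
        for r in (rep.ordinal, rep.dichotomous):
            for sx in r.means_by_sex.index:
                mean = r.means_by_sex.loc[sx, "mean"]
                sd = r.means_by_sex.loc[sx, "std"]
                cell = f"{mean:.3f} ({sd:.3f})"
                auc_txt = ""
                if sx in r.auc_by_sex:
                    a = r.auc_by_sex[sx]
                    auc_txt = f"{a.auc:.3f} ({a.ci_low:.3f}, {a.ci_high:.3f})"
                lines.append(f"{r.scheme:<13}{sx:<9}{cell:<18}{auc_txt:<24}")
        lines.append("")
        lines.append(
            f"sex-adjusted means: ordinal {rep.anova.adjusted_means['ordinal']:.4f}, "
            f"dichotomous {rep.anova.adjusted_means['dichotomous']:.4f} "
            f"(ANOVA scheme p = {rep.anova.p_scheme:.3g})"
        )
        lines.append("")
        lines.append("Cox proportional hazards (time to death)")
        lines.append("-" * w)
        lines.append(
            f"{'scheme':<13}{'covariate':<13}{'HR':>8}{'95% CI':>20}{'p':>12}"
        )
        for r in (rep.ordinal, rep.dichotomous):
            for cov, row in r.cox.summary.iterrows():
                ci = f"({row['hr_ci_low']:.3f}, {row['hr_ci_high']:.3f})"
                lines.append(
                    f"{r.scheme:<13}{cov:<13}{row['hr']:>8.3f}{ci:>20}"
                    f"{row['p']:>12.3g}"
                )
        nonprop = [
            f"{r.scheme}:{cov}"
            for r in (rep.ordinal, rep.dichotomous)
            for cov, flag in zip(
                r.cox.summary.index, r.cox.proportionality["non_proportional"]
            )
            if flag
        ]
        if nonprop:
            lines.append(
                "proportionality advisory (Schoenfeld trend p < 0.05): "
                + ", ".join(nonprop)
            )
        lines.append("")
        lines.append("Paired differences (ordinal vs dichotomous)")
        lines.append("-" * w)
        lines.append(
            f"|d mean FI| = {rep.delta_mean_fi:.4f} "
            f"({rep.delta_mean_deficits:.2f} deficits of {rep.n_items})"
        )
        lines.append(f"|d HR per 0.01 FI| = {rep.delta_hr_fi:.4f}")
        by_sex = ", ".join(
            f"{sx} {d:.4f}" for sx, d in rep.delta_auc_by_sex.items()
        )
        lines.append(f"|d AUC| = {rep.delta_auc:.4f}" + (f" ({by_sex})" if by_sex else ""))
        lines.append("=" * w)
        return "\n".join(lines)

    def to_files(self, outdir: str | Path, emit_roc_points: bool = False) -> None:
        """Write the report bundle: FI scores, means/AUC and HR tables,
        machine-readable report JSON, manifest, optional ROC coordinates."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fi_table.to_csv(outdir / "fi_scores.csv")
        rep = self.report

        rows = []
        for r in (rep.ordinal, rep.dichotomous):
            for sx in r.means_by_sex.index:
                row = {
                    "scheme": r.scheme,
                    "sex": sx,
                    "mean_fi": r.means_by_sex.loc[sx, "mean"],
                    "sd_fi": r.means_by_sex.loc[sx, "std"],
                    "n": int(r.means_by_sex.loc[sx, "n"]),
                }
                if sx in r.auc_by_sex:
                    a = r.auc_by_sex[sx]
                    row.update(
                        auc=a.auc, auc_ci_low=a.ci_low, auc_ci_high=a.ci_high
                    )
                rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "means_and_auc.csv", index=False)

        hr_rows = []
        for r in (rep.ordinal, rep.dichotomous):
            t = r.cox.summary.reset_index()
            t.insert(0, "scheme", r.scheme)
            hr_rows.append(t)
        pd.concat(hr_rows).to_csv(outdir / "cox_hazard_ratios.csv", index=False)

        (outdir / "comparison_report.json").write_text(
            json.dumps(rep.to_dict(), indent=1, default=float)
        )
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, default=str)
        )
        if emit_roc_points:
            surv = self.model.survival.loc[self.fi_table.index[~self.fi_table["excluded"]]]
            for r in (rep.ordinal, rep.dichotomous):
                pts = roc_curve_points(r.fi, surv["event"])
                pts.to_csv(outdir / f"roc_points_{r.scheme}.csv", index=False)


class FrailtyComparison:
    """Paired frailty-index comparison model for one cohort.

    Parameters
    ----------
    raw_table
        One row per individual; schema item columns plus ``age`` and ``sex``.
    survival
        Columns ``time`` (years), ``event`` (1 = died within follow-up),
        indexed like ``raw_table`` (``age``/``sex`` are taken from
        ``raw_table`` if absent).
    schema
        The coding book defining both regimes for every item.
    missing_threshold
        Exclusion rule: drop individuals missing strictly more than this
        fraction of items (default 0.20).
    """

    def __init__(
        self,
        raw_table: pd.DataFrame,
        survival: pd.DataFrame,
        schema: CodingSchema,
        missing_threshold: float = 0.20,
    ) -> None:
        if len(raw_table) == 0:
            raise ValueError("empty cohort")
        missing_cols = [c for c in ("age", "sex") if c not in raw_table.columns]
        if missing_cols:
            raise KeyError(f"raw table lacks required column(s): {missing_cols}")
        survival = survival.copy()
        for col in ("age", "sex"):
            if col not in survival.columns:
                survival[col] = raw_table[col]
        self.raw_table = raw_table
        self.survival = survival.loc[raw_table.index]
        self.schema = schema
        self.missing_threshold = missing_threshold

    @classmethod
    def from_preset(
        cls, name: str, n: int = 2000, seed: int = 0, **kwargs
    ) -> "FrailtyComparison":
        """Build the model on a freshly generated preset synthetic cohort."""
        from .simulate import generate_cohort, preset_spec

        cohort = generate_cohort(preset_spec(name, n=n, seed=seed))
        model = cls(cohort.raw_table, cohort.survival, cohort.schema, **kwargs)
        model.cohort = cohort
        return model

    def screen(self) -> pd.DataFrame:
        """Advisory item-screening report for this cohort."""
        return screen_variables(self.raw_table, self.schema)

    def fit(self) -> FrailtyComparisonResults:
        ord_matrix = encode_responses(self.raw_table, self.schema, "ordinal")
        dich_matrix = encode_responses(self.raw_table, self.schema, "dichotomous")
        fi_ord = compute_fi(ord_matrix, self.missing_threshold)
        fi_dich = compute_fi(dich_matrix, self.missing_threshold)

        excluded = fi_ord["excluded"] | fi_dich["excluded"]
        fi_table = pd.DataFrame(
            {
                "fi_ordinal": fi_ord["fi"].where(~excluded),
                "fi_dichotomous": fi_dich["fi"].where(~excluded),
                "n_nonmissing_ordinal": fi_ord["n_nonmissing"],
                "n_nonmissing_dichotomous": fi_dich["n_nonmissing"],
                "excluded": excluded,
                "exclusion_disagreement": fi_ord["excluded"] != fi_dich["excluded"],
            },
            index=self.raw_table.index,
        )
        keep = ~excluded
        if keep.sum() == 0:
            raise ValueError("all individuals excluded by the missingness rule")
        surv = self.survival.loc[keep]
        sex = normalize_sex(surv["sex"])

        rep_ord = build_scheme_report("ordinal", fi_ord.loc[keep, "fi"], surv)
        rep_dich = build_scheme_report("dichotomous", fi_dich.loc[keep, "fi"], surv)
        anova = mean_fi_anova(rep_ord.fi, rep_dich.fi, sex)
        report = compare_indices(rep_ord, rep_dich, len(self.schema), anova=anova)

        manifest = {
            "study_id": self.schema.study_id,
            "schema_variant": self.schema.variant,
            "package_version": __import__("frailtyindex").__version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "missing_threshold": self.missing_threshold,
            "input_checksums": {
                "raw_table": _frame_checksum(self.raw_table),
                "survival": _frame_checksum(self.survival),
            },
            "n_read": int(len(self.raw_table)),
            "n_encoded": int(len(self.raw_table)),
            "n_excluded": int(excluded.sum()),
            "n_modeled": int(keep.sum()),
            "n_events": int(surv["event"].sum()),
            "n_items": len(self.schema),
            "unmapped_responses": {
                "ordinal": ord_matrix.unmapped_by_item,
                "dichotomous": dich_matrix.unmapped_by_item,
            },
        }
        assert manifest["n_modeled"] == manifest["n_read"] - manifest["n_excluded"]
        return FrailtyComparisonResults(
            model=self,
            fi_table=fi_table,
            report=report,
            schema_diagnostics=validate_schema(self.schema),
            manifest=manifest,
        )
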