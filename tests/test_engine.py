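"""Encoding and frailty-index scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from frailtyindex import (
    DeficitMatrix,
    SchemaError,
    compute_fi,
    encode_responses,
    load_packaged_schema,
)
from frailtyindex.engine import screen_variables
from frailtyindex.schema import schema_from_dict

from conftest import random_deficit_matrix


def _one_row_table(schema, overrides):
    row = {name: None for name in schema.item_names}
    row.update(overrides)
    return pd.DataFrame([row])


class TestEncoding:
    def test_graded_assistance_coding(self, nshs_schema):
        """'yes with assistance' grades to 0.5 ordinally but counts as no
        deficit dichotomously (any 'yes' is a 0)."""
        table = _one_row_table(
            nshs_schema, {"Able to go outside in good weather": "yes with assistance"}
        )
        col = "Able to go outside in good weather"
        ordinal = encode_responses(table, nshs_schema, "ordinal")
        dich = encode_responses(table, nshs_schema, "dichotomous")
        assert ordinal.values.loc[0, col] == 0.5
        assert dich.values.loc[0, col] == 0.0

    def test_self_rated_health_fair(self, share_schema):
        table = _one_row_table(share_schema, {"Self-rated health": "fair"})
        assert (
            encode_responses(table, share_schema, "ordinal").values.loc[
                0, "Self-rated health"
            ]
            == 0.75
        )
        assert (
            encode_responses(table, share_schema, "dichotomous").values.loc[
                0, "Self-rated health"
            ]
            == 1.0
        )

    @pytest.mark.parametrize(
        "sbp, ordinal_value, dich_value",
        [
            (85.0, 0.5, 1.0),
            (90.0, 0.0, 0.0),
            (139.9, 0.0, 0.0),
            (140.0, 0.5, 0.0),  # dichotomous keeps 140 in the healthy range
            (150.0, 0.5, 1.0),
            (160.0, 0.5, 1.0),
            (161.0, 1.0, 1.0),
        ],
    )
    def test_blood_pressure_bins(self, nshs_schema, sbp, ordinal_value, dich_value):
        table = _one_row_table(nshs_schema, {"Systolic blood pressure": sbp})
        assert (
            encode_responses(table, nshs_schema, "ordinal").values.loc[
                0, "Systolic blood pressure"
            ]
            == ordinal_value
        )
        assert (
            encode_responses(table, nshs_schema, "dichotomous").values.loc[
                0, "Systolic blood pressure"
            ]
            == dich_value
        )

    @pytest.mark.parametrize(
        "mmse, dich_value", [(23, 1.0), (24, 0.0), (25, 0.0), (30, 0.0)]
    )
    def test_mmse_dichotomous_cutoff(self, yale_schema, mmse, dich_value):
        """The conventional MMSE cutoff: scores of 24+ are non-deficit."""
        table = _one_row_table(
            yale_schema, {"MMSE": mmse, "sex": "female", "age": 80.0}
        )
        coded = encode_responses(table, yale_schema, "dichotomous")
        assert coded.values.loc[0, "MMSE"] == dich_value

    @pytest.mark.parametrize(
        "pace, dich_value", [(15.9, 0.0), (16.0, 0.0), (16.1, 1.0)]
    )
    def test_gait_boundary_belongs_to_lower_bin(self, yale_schema, pace, dich_value):
        """Printed '<=16 = 0, >16 = 1' keeps 16 seconds non-deficit."""
        table = _one_row_table(
            yale_schema, {"Usual pace": pace, "sex": "male", "age": 75.0}
        )
        coded = encode_responses(table, yale_schema, "dichotomous")
        assert coded.values.loc[0, "Usual pace"] == dich_value

    def test_sex_specific_peak_flow(self, yale_schema):
        table = pd.DataFrame(
            {name: [None, None] for name in yale_schema.item_names}
            | {"Peak flow": [450.0, 450.0], "sex": ["male", "female"], "age": [75, 75]}
        )
        ordinal = encode_responses(table, yale_schema, "ordinal")
        # 450 L/min: mid-range for a man (0.5), best bin for a woman (0)
        assert ordinal.values.loc[0, "Peak flow"] == 0.5
        assert ordinal.values.loc[1, "Peak flow"] == 0.0

    def test_sex_specific_requires_sex_column(self, yale_schema):
        table = _one_row_table(yale_schema, {"Peak flow": 400.0})
        with pytest.raises(SchemaError, match="sex"):
            encode_responses(table, yale_schema, "ordinal")

    def test_unrecognized_label_becomes_missing_with_warning(self, nshs_schema):
        table = _one_row_table(nshs_schema, {"Diabetes": "maybe"})
        coded = encode_responses(table, nshs_schema, "ordinal")
        assert np.isnan(coded.values.loc[0, "Diabetes"])
        assert coded.unmapped_by_item == {"Diabetes": 1}
        assert coded.n_unmapped == 1

    def test_declared_missing_labels_are_not_warned(self, nshs_schema):
        table = _one_row_table(nshs_schema, {"Diabetes": "don't know"})
        coded = encode_responses(table, nshs_schema, "ordinal")
        assert np.isnan(coded.values.loc[0, "Diabetes"])
        assert coded.n_unmapped == 0

    def test_missing_schema_item_raises(self, nshs_schema):
        table = pd.DataFrame({"Diabetes": ["no"]})
        with pytest.raises(KeyError, match="schema item"):
            encode_responses(table, nshs_schema, "ordinal")


class TestComputeFI:
    def test_no_deficits_scores_zero(self):
        m = pd.DataFrame(np.zeros((1, 23)))
        assert compute_fi(m)["fi"].iloc[0] == 0.0

    def test_direct_formula(self):
        vals = np.zeros((1, 33))
        vals[0, :7] = 0.5
        assert vals.sum() == 3.5
        fi = compute_fi(pd.DataFrame(vals))["fi"].iloc[0]
        assert fi == pytest.approx(3.5 / 33)

    def test_exclusion_above_20_percent(self):
        vals = np.zeros((1, 23))
        vals[0, :5] = np.nan  # 5/23 = 21.7% missing
        res = compute_fi(pd.DataFrame(vals))
        assert bool(res["excluded"].iloc[0])
        assert np.isnan(res["fi"].iloc[0])

    def test_exactly_20_percent_retained(self):
        vals = np.full((1, 10), 0.5)
        vals[0, :2] = np.nan  # exactly 20%
        res = compute_fi(pd.DataFrame(vals))
        assert not bool(res["excluded"].iloc[0])
        assert res["fi"].iloc[0] == pytest.approx(0.5)

    def test_all_missing_excluded_regardless_of_threshold(self):
        vals = np.full((1, 5), np.nan)
        res = compute_fi(pd.DataFrame(vals), missing_threshold=0.99)
        assert bool(res["excluded"].iloc[0])

    def test_matches_per_individual_loop(self, rng):
        """The vectorized FI agrees with an independent scalar loop."""
        for _ in range(20):
            n = int(rng.integers(1, 120))
            k = int(rng.integers(2, 40))
            df = random_deficit_matrix(rng, n, k, missing_rate=0.3)
            res = compute_fi(df, missing_threshold=0.2)
            for i in range(n):
                row = df.iloc[i]
                m = int(row.notna().sum())
                if m == 0 or (k - m) / k > 0.2:
                    assert bool(res["excluded"].iloc[i])
                else:
                    expected = sum(x for x in row if not np.isnan(x)) / m
                    assert abs(res["fi"].iloc[i] - expected) < 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_fi(pd.DataFrame())

    @given(
        st.integers(2, 30),
        st.integers(0, 29),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_raising_a_cell_never_lowers_fi(self, k, j, v_low, v_high):
        """Monotonicity: increasing one deficit value cannot decrease FI."""
        j = j % k
        lo, hi = sorted((v_low, v_high))
        base = np.full((1, k), 0.3)
        a, b = base.copy(), base.copy()
        a[0, j], b[0, j] = lo, hi
        fi_a = compute_fi(pd.DataFrame(a))["fi"].iloc[0]
        fi_b = compute_fi(pd.DataFrame(b))["fi"].iloc[0]
        assert fi_b >= fi_a - 1e-15


class TestSchemeAgreement:
    def _binary_schema(self, k):
        return schema_from_dict(
            {
                "study_id": "binary",
                "variables": [
                    {
                        "name": f"item_{j}",
                        "ordinal": {
                            "levels": [
                                {"label": "no", "value": 0},
                                {"label": "yes", "value": 1},
                            ]
                        },
                        "dichotomous": {
                            "levels": [
                                {"label": "no", "value": 0},
                                {"label": "yes", "value": 1},
                            ]
                        },
                    }
                    for j in range(k)
                ],
            }
        )

    def test_identical_maps_give_identical_fi(self, rng):
        """With all-binary identical codings the two schemes agree exactly."""
        schema = self._binary_schema(12)
        raw = pd.DataFrame(
            rng.choice(["no", "yes", None], p=[0.6, 0.3, 0.1], size=(80, 12)),
            columns=schema.item_names,
        )
        fi_o = compute_fi(encode_responses(raw, schema, "ordinal"))
        fi_d = compute_fi(encode_responses(raw, schema, "dichotomous"))
        pd.testing.assert_frame_equal(
            fi_o.drop(columns="scheme"), fi_d.drop(columns="scheme")
        )

    def test_scheme_difference_bound(self, share_schema, rng):
        """|FI_ord - FI_dich| <= (number of items whose codings differ for
        the response) / (non-missing count), per individual."""
        from frailtyindex import generate_cohort, preset_spec

        cohort = generate_cohort(preset_spec("share_like", n=300, seed=11))
        mo = encode_responses(cohort.raw_table, cohort.schema, "ordinal")
        md = encode_responses(cohort.raw_table, cohort.schema, "dichotomous")
        fo = compute_fi(mo)
        fd = compute_fi(md)
        differs = (mo.values != md.values) & mo.values.notna()
        p = differs.sum(axis=1)
        m = mo.values.notna().sum(axis=1)
        keep = ~(fo["excluded"] | fd["excluded"])
        gap = (fo["fi"] - fd["fi"]).abs()[keep]
        assert (gap <= (p / m)[keep] + 1e-12).all()


class TestScreening:
    def _screen_table(self, rng, n=800):
        schema = schema_from_dict(
            {
                "study_id": "screen",
                "variables": [
                    {
                        "name": name,
                        "ordinal": {
                            "levels": [
                                {"label": "no", "value": 0},
                                {"label": "yes", "value": 1},
                            ]
                        },
                        "dichotomous": {
                            "levels": [
                                {"label": "no", "value": 0},
                                {"label": "yes", "value": 1},
                            ]
                        },
                    }
                    for name in ("saturated", "leaky", "age_null")
                ],
            }
        )
        age = rng.uniform(40, 95, size=n)
        old = age >= 80
        sat = np.where(
            rng.random(n) < np.where(old, 0.9, 0.3), "yes", "no"
        ).astype(object)
        leaky = np.where(rng.random(n) < 0.3, "yes", "no").astype(object)
        leaky[rng.random(n) < 0.10] = None
        null = np.where(rng.random(n) < 0.3, "yes", "no").astype(object)
        table = pd.DataFrame(
            {"age": age, "saturated": sat, "leaky": leaky, "age_null": null}
        )
        return table, schema

    def test_flags(self, rng):
        table, schema = self._screen_table(rng)
        rep = screen_variables(table, schema)
        assert bool(rep.loc["saturated", "saturated"])
        assert rep.loc["leaky", "too_missing"]
        assert rep.loc["age_null", "not_age_related"]
        assert not rep.loc["saturated", "not_age_related"]
        assert not rep.loc["age_null", "too_missing"]

    def test_saturation_not_assessable_without_oldest_old(self, rng):
        table, schema = self._screen_table(rng)
        young = table[table["age"] < 75].reset_index(drop=True)
        rep = screen_variables(young, schema)
        assert rep["saturated"].isna().all()

    def test_requires_age_column(self, rng):
        table, schema = self._screen_table(rng)
        with pytest.raises(KeyError, match="age"):
            screen_variables(table.drop(columns="age"), schema)
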