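"""Range-interval niche overlap, cumulative overlap, baseline and LRRs."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmsens import (
    ClimateStack,
    GridGeometry,
    island_climate_range,
    lrr,
    pair_lrrs,
    select_baseline,
    variable_overlap,
    weighted_cumulative_overlap,
)

props = st.floats(0.0, 1.0, allow_nan=False)


class TestIslandRange:
    def test_constant_band(self):
        geom = GridGeometry(n_rows=1, n_cols=3)
        stack = ClimateStack("i", geom, {"V": np.full((1, 3), 5.0)})
        assert island_climate_range(stack).bounds["V"] == (5.0, 5.0)

    def test_min_max_extraction(self):
        geom = GridGeometry(n_rows=1, n_cols=3)
        stack = ClimateStack("i", geom, {"V": np.array([[1.0, 2.0, 9.0]])})
        assert island_climate_range(stack).bounds["V"] == (1.0, 9.0)

    def test_masked_outlier_excluded(self):
        geom = GridGeometry(n_rows=1, n_cols=3)
        mask = np.array([[True, True, False]])
        stack = ClimateStack(
            "i", geom, {"V": np.array([[1.0, 2.0, 99.0]])}, mask=mask
        )
        assert island_climate_range(stack).bounds["V"] == (1.0, 2.0)

    def test_empty_mask_rejected(self):
        geom = GridGeometry(n_rows=1, n_cols=2)
        stack = ClimateStack(
            "i", geom, {"V": np.zeros((1, 2))}, mask=np.zeros((1, 2), bool)
        )
        with pytest.raises(ValueError):
            island_climate_range(stack)


class TestVariableOverlap:
    def test_all_inside(self):
        assert variable_overlap(np.linspace(1, 2, 20), (0, 3)) == 100.0

    def test_none_inside(self):
        assert variable_overlap(np.linspace(10, 12, 20), (0, 3)) == 0.0

    def test_partial_count(self):
        values = np.concatenate([np.full(7, 1.0), np.full(13, 99.0)])
        assert variable_overlap(values, (0, 2)) == 35.0

    def test_bounds_inclusive(self):
        assert variable_overlap([1.0, 2.0, 3.0], (1.0, 2.0)) == pytest.approx(
            200 / 3
        )

    def test_zero_records_rejected(self):
        with pytest.raises(ValueError):
            variable_overlap([], (0, 1))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_per_record_count(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 2, 50)
        lo, hi = sorted(rng.normal(0, 2, 2))
        expected = 100.0 * sum(lo <= v <= hi for v in values) / 50
        assert variable_overlap(values, (lo, hi)) == pytest.approx(expected)

    def test_widening_range_never_decreases_overlap(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 100)
        o1 = variable_overlap(values, (-0.5, 0.5))
        o2 = variable_overlap(values, (-1.0, 1.0))
        assert o2 >= o1


class TestCumulativeOverlap:
    def test_equal_overlaps_for_any_weights(self):
        o = {v: 40.0 for v in "abcd"}
        w = {"a": 0.9, "b": 0.01, "c": 0.05, "d": 0.04}
        assert weighted_cumulative_overlap(o, w) == pytest.approx(40.0)

    def test_point_mass_weights(self):
        o = {"a": 10.0, "b": 90.0}
        assert weighted_cumulative_overlap(o, {"a": 1.0, "b": 0.0}) == 10.0

    def test_normalised_weight_arithmetic(self):
        o = dict(zip("abcd", (10.0, 90.0, 50.0, 50.0)))
        w = dict(zip("abcd", (0.3, 0.1, 0.1, 0.1)))
        # 10*0.5 + 90/6 + 50/6 + 50/6 = 110/3
        assert weighted_cumulative_overlap(o, w) == pytest.approx(110 / 3)

    def test_zero_importances_weight_equally(self):
        o = {"a": 0.0, "b": 100.0}
        assert weighted_cumulative_overlap(o, {"a": 0.0, "b": 0.0}) == 50.0

    def test_invariant_to_importance_rescaling(self):
        o = dict(zip("abcd", (10.0, 90.0, 50.0, 50.0)))
        w = dict(zip("abcd", (0.3, 0.1, 0.1, 0.1)))
        w10 = {k: 10 * v for k, v in w.items()}
        assert weighted_cumulative_overlap(o, w) == pytest.approx(
            weighted_cumulative_overlap(o, w10)
        )

    def test_bounded_by_extreme_overlaps(self):
        rng = np.random.default_rng(2)
        o = {v: float(rng.uniform(0, 100)) for v in "abcd"}
        w = {v: float(rng.uniform(0, 1)) for v in "abcd"}
        om = weighted_cumulative_overlap(o, w)
        assert min(o.values()) - 1e-9 <= om <= max(o.values()) + 1e-9

    def test_variable_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cumulative_overlap({"a": 1.0}, {"b": 1.0})


class TestBaseline:
    def _table(self, means):
        rows = []
        for model, m in means.items():
            for i in range(4):
                rows.append(
                    {
                        "predictor_set": model,
                        "species": f"s{i % 2}",
                        "island": f"i{i // 2}",
                        "omega": m + i,  # same increments: mean order = m order
                    }
                )
        return pd.DataFrame(rows)

    def test_dominating_model_selected(self):
        t = self._table({"m1": 10.0, "m2": 50.0, "m3": 20.0})
        assert select_baseline(t) == "m2"

    def test_tie_breaks_to_first_id(self):
        t = self._table({"mB": 30.0, "mA": 30.0})
        assert select_baseline(t) == "mA"

    def test_hand_computed_argmax(self):
        t = pd.DataFrame(
            {
                "predictor_set": ["a", "a", "b", "b", "c", "c"],
                "species": ["s1", "s2"] * 3,
                "island": ["i"] * 6,
                "omega": [10, 30, 25, 25, 40, 0],
            }
        )
        # means: a 20, b 25, c 20 -> b
        assert select_baseline(t) == "b"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_baseline(pd.DataFrame(columns=["predictor_set", "omega"]))


class TestLrr:
    def test_identity_at_equal_proportions(self):
        for x in (0.0, 0.3, 1.0):
            assert lrr(x, x) == 0.0

    def test_closed_form_zero_to_one(self):
        assert lrr(0.0, 1.0) == pytest.approx(math.log(1.00001 / 0.00001), abs=1e-9)

    def test_closed_form_quarter_half(self):
        assert lrr(0.25, 0.5) == pytest.approx(
            math.log(0.50001 / 0.25001), abs=1e-9
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lrr(-0.1, 0.5)
        with pytest.raises(ValueError):
            lrr(0.5, 1.2)

    @given(props, props)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_antisymmetry(self, a, b):
        assert lrr(a, b) == pytest.approx(-lrr(b, a), abs=1e-12)


class TestPairLrrs:
    def _tables(self):
        rows, orows = [], []
        for sp in ("a", "b"):
            for isl in ("x", "y"):
                for i, model in enumerate(("m1", "m2", "m3")):
                    rows.append(
                        {
                            "species": sp,
                            "island": isl,
                            "predictor_set": model,
                            "fraction_suitable": 0.2 + 0.1 * i,
                        }
                    )
                    orows.append(
                        {
                            "species": sp,
                            "island": isl,
                            "predictor_set": model,
                            "omega": 30.0 + 10 * i,
                        }
                    )
        return pd.DataFrame(rows), pd.DataFrame(orows)

    def test_cardinality(self):
        suit, om = self._tables()
        out = pair_lrrs(suit, om, "m1")
        assert len(out) == 8  # 2 species x 2 islands x 2 comparisons

    def test_identical_model_gives_zero_lrrs(self):
        suit, om = self._tables()
        suit.loc[suit["predictor_set"] == "m2", "fraction_suitable"] = 0.2
        om.loc[om["predictor_set"] == "m2", "omega"] = 30.0
        out = pair_lrrs(suit, om, "m1")
        m2 = out[out["predictor_set"] == "m2"]
        assert np.allclose(m2["lrr_suitability"], 0.0)
        assert np.allclose(m2["lrr_overlap"], 0.0)

    def test_hand_computed_row(self):
        suit, om = self._tables()
        out = pair_lrrs(suit, om, "m1")
        row = out[(out["species"] == "a") & (out["island"] == "x") & (
            out["predictor_set"] == "m2")].iloc[0]
        assert row["lrr_suitability"] == pytest.approx(
            math.log(0.30001 / 0.20001), abs=1e-9
        )
        assert row["lrr_overlap"] == pytest.approx(
            math.log(0.40001 / 0.30001), abs=1e-9
        )

    def test_failed_rows_dropped_and_counted(self):
        suit, om = self._tables()
        suit.loc[0, "fraction_suitable"] = np.nan  # a/x baseline m1 missing
        out = pair_lrrs(suit, om, "m1")
        assert len(out) == 6
        assert out.attrs["n_dropped"] == 2

    def test_missing_baseline_rejected(self):
        suit, om = self._tables()
        with pytest.raises(ValueError):
            pair_lrrs(suit, om, "nope")
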