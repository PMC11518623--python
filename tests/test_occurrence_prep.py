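"""Cleaning filters, grid aggregation, thinning and pseudo-absence draws."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from sdmsens import (
    PrepConfig,
    ReferencePoints,
    clean_records,
    draw_pseudo_absences,
    quadrant_regions,
    snap_to_grid,
    thin_records,
    uniform_bias,
)
from sdmsens.occurrences import (
    InsufficientBackgroundError,
    max_retained_bruteforce,
)


def make_table(lon, lat, year=2000, unc=10.0, basis="HUMAN_OBSERVATION", species="s"):
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    return pd.DataFrame(
        {
            "species": species,
            "decimalLongitude": lon,
            "decimalLatitude": np.atleast_1d(np.asarray(lat, dtype=float)),
            "year": year,
            "coordinateUncertaintyInMeters": unc,
            "basisOfRecord": basis,
        }
    )


class TestCleaning:
    def test_pre_cutoff_year_removed(self):
        t = make_table([50.0], [30.0], year=1975)
        kept, audit = clean_records(t, PrepConfig())
        assert len(kept) == 0 and audit["year"] == 1

    def test_zero_zero_radius(self):
        # (0.10, 0.12) lies ~0.156 degrees from the origin, inside 0.5
        t = make_table([0.10, 5.0], [0.12, 5.0001])
        kept, audit = clean_records(t, PrepConfig())
        assert audit["zero_zero"] == 1
        assert len(kept) == 1

    def test_empty_table_empty_audit(self):
        t = make_table([], [])
        kept, audit = clean_records(t, PrepConfig())
        assert len(kept) == 0
        assert all(v == 0 for v in audit.values())

    def test_missing_column_schema_error(self):
        t = make_table([1.0], [2.0]).drop(columns=["year"])
        with pytest.raises(KeyError, match="year"):
            clean_records(t, PrepConfig())

    def test_audit_sums_to_removed_rows(self):
        refs = ReferencePoints()
        t = pd.concat(
            [
                make_table([50.0], [30.0]),  # clean
                make_table([50.0], [30.0], year=1900),  # year
                make_table([50.0], [30.0], unc=5000.0),  # uncertainty
                make_table([33.0], [33.0]),  # equal lon/lat
                make_table([0.05], [0.05]),  # near 0/0 (also equal? no: equal first)
                make_table([refs.capitals[0][0] + 0.01], [refs.capitals[0][1]]),
                make_table([refs.hq[0][0]], [refs.hq[0][1] + 0.1]),
            ],
            ignore_index=True,
        )
        kept, audit = clean_records(t, PrepConfig())
        assert sum(audit.values()) == len(t) - len(kept)
        assert audit["year"] == 1 and audit["uncertainty"] == 1
        assert audit["capital"] == 1 and audit["hq"] == 1

    def test_earlier_filter_wins(self):
        # a 1900 record sitting on the equal-lon-lat diagonal is charged to
        # the year filter only
        t = make_table([20.0], [20.0], year=1900)
        _, audit = clean_records(t, PrepConfig())
        assert audit["year"] == 1 and audit["equal_lon_lat"] == 0

    def test_order_stability_under_row_permutation(self):
        rng = np.random.default_rng(0)
        t = make_table(
            rng.uniform(-10, 60, 80), rng.uniform(-10, 60, 80),
            year=rng.integers(1950, 2020, 80),
        )
        cfg = PrepConfig()
        kept1, audit1 = clean_records(t, cfg)
        perm = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        kept2, audit2 = clean_records(perm, cfg)
        assert audit1 == audit2
        key = ["decimalLongitude", "decimalLatitude", "year"]
        assert set(map(tuple, kept1[key].to_numpy())) == set(
            map(tuple, kept2[key].to_numpy())
        )

    def test_disallowed_basis_removed(self):
        t = make_table([10.0, 11.0], [20.0, 21.0])
        t.loc[0, "basisOfRecord"] = "FOSSIL_SPECIMEN"
        kept, audit = clean_records(t, PrepConfig())
        assert audit["basis_of_record"] == 1 and len(kept) == 1


class TestSnapToGrid:
    def test_three_records_one_cell_collapse_to_centre(self, small_stack):
        t = make_table([5.1, 5.4, 5.9, 12.3], [7.2, 7.6, 7.3, 2.8])
        snapped, audit = snap_to_grid(t, small_stack)
        assert len(snapped) == 2  # three in cell (7,5) plus one in (2,12)
        centres = set(
            zip(snapped["decimalLongitude"], snapped["decimalLatitude"])
        )
        assert centres == {(5.5, 7.5), (12.5, 2.5)}
        assert audit["aggregated"] == 2

    def test_idempotent_on_reapplication(self, small_stack):
        t = make_table([3.2, 11.7, 25.0], [3.9, 18.2, 30.5])
        once, _ = snap_to_grid(t, small_stack)
        twice, audit = snap_to_grid(once, small_stack)
        pd.testing.assert_frame_equal(once, twice)
        assert audit["aggregated"] == 0

    def test_outside_extent_dropped_and_counted(self, small_stack):
        t = make_table([5.0, -3.0], [5.0, 5.0])
        snapped, audit = snap_to_grid(t, small_stack)
        assert len(snapped) == 1 and audit["outside_extent"] == 1


class TestThinning:
    def test_single_record_retained(self):
        t = make_table([1.0], [1.0])
        out = thin_records(t, 10.0, reps=5, seed=0)
        assert len(out) == 1

    def test_collinear_0_6_12_keeps_endpoints(self):
        t = make_table([0.0, 6.0, 12.0], [0.0, 0.0, 0.0])
        out = thin_records(t, 10.0, reps=20, seed=1, metric="euclidean")
        assert sorted(out["decimalLongitude"]) == [0.0, 12.0]

    def test_already_thinned_unchanged(self):
        t = make_table([0.0, 20.0, 40.0], [0.0, 0.0, 0.0])
        out = thin_records(t, 10.0, reps=3, seed=0, metric="euclidean")
        pd.testing.assert_frame_equal(out, t)

    def test_reps_below_one_rejected(self):
        t = make_table([0.0], [0.0])
        with pytest.raises(ValueError):
            thin_records(t, 10.0, reps=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.uniform(0, 30, 40), rng.uniform(0, 30, 40))
        a = thin_records(t, 8.0, reps=10, seed=42, metric="euclidean")
        b = thin_records(t, 8.0, reps=10, seed=42, metric="euclidean")
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        t = make_table(rng.uniform(0, 25, n), rng.uniform(0, 25, n))
        out = thin_records(t, 10.0, reps=20, seed=seed, metric="euclidean")
        assert len(out) == max_retained_bruteforce(t, 10.0, metric="euclidean")


class TestPseudoAbsences:
    def _presences_in_cells(self, stack, cells):
        rows = np.array([r for r, _ in cells])
        cols = np.array([c for _, c in cells])
        x, y = stack.geometry.center_of(rows, cols)
        return make_table(x, y)

    def test_floor_of_100_for_sparse_species(self, small_stack, flat_bias):
        cells = [(i, j) for i in range(8) for j in range(5)]  # 40 presences
        pres = self._presences_in_cells(small_stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=2)
        sets = draw_pseudo_absences(
            pres, small_stack, flat_bias, None, cfg, seed=0
        )
        assert len(sets) == 2
        assert all(len(s) == 100 for s in sets)

    def test_matches_presence_count_when_large(self, small_stack, flat_bias):
        cells = [(i, j) for i in range(20) for j in range(25)]  # 500 presences
        pres = self._presences_in_cells(small_stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=1)
        sets = draw_pseudo_absences(pres, small_stack, flat_bias, None, cfg, seed=0)
        assert len(sets[0]) == 500

    def test_region_restriction(self, small_stack, flat_bias):
        # 12 presences in quadrant 0, 3 in quadrant 3: only quadrant 0 is
        # an eligible background region
        regions = quadrant_regions(small_stack)
        cells = [(i, 0) for i in range(12)] + [(30, j) for j in (30, 32, 34)]
        pres = self._presences_in_cells(small_stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=3, pa_floor=50)
        sets = draw_pseudo_absences(pres, small_stack, flat_bias, regions, cfg, 1)
        for s in sets:
            assert (regions[s.cells["row"], s.cells["col"]] == 0).all()

    def test_presence_cells_never_drawn(self, small_stack, flat_bias):
        cells = [(i, j) for i in range(10) for j in range(4)]
        pres = self._presences_in_cells(small_stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=5)
        sets = draw_pseudo_absences(pres, small_stack, flat_bias, None, cfg, 2)
        pres_set = set(cells)
        for s in sets:
            drawn = set(zip(s.cells["row"], s.cells["col"]))
            assert not (drawn & pres_set)

    def test_insufficient_background_error(self, flat_bias):
        from sdmsens import ClimateStack, GridGeometry

        geom = GridGeometry(n_rows=6, n_cols=6)
        stack = ClimateStack("tiny", geom, {"A": np.zeros((6, 6))})
        cells = [(i, j) for i in range(6) for j in range(3)]  # 18 presences
        pres = self._presences_in_cells(stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=1)  # needs 100 PAs
        with pytest.raises(InsufficientBackgroundError):
            draw_pseudo_absences(
                pres, stack, uniform_bias(stack), None, cfg, seed=0
            )

    def test_uniform_bias_gives_uniform_draws(self, small_stack):
        # constant bias over the candidate pool: cell counts across many
        # draws pass a chi-square goodness-of-fit test against uniformity
        cells = [(0, j) for j in range(11)]  # 11 presences (> 10 rule)
        pres = self._presences_in_cells(small_stack, cells)
        cfg = PrepConfig(metric="euclidean", pa_draws=200, pa_floor=5)
        sets = draw_pseudo_absences(
            pres, small_stack, uniform_bias(small_stack), None, cfg, seed=7
        )
        counts = np.zeros(small_stack.shape)
        for s in sets:
            counts[s.cells["row"], s.cells["col"]] += 1
        pool = np.ones(small_stack.shape, dtype=bool)
        pool[tuple(zip(*cells))] = False
        observed = counts[pool]
        stat, p = chisquare(observed)
        assert p > 0.01
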