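"""Occurrence cleaning, grid aggregation, spatial thinning, pseudo-absences.

The cleaning chain applies the standard record-quality filters of
presence-only archives in a fixed, documented order (basis-of-record, then
year, coordinate uncertainty, equal lon/lat, 0/0 neighbourhood, capital,
centroid, institution, headquarters radii); a record removed by an earlier
filter is never re-counted by a later one, so the audit counts sum exactly
to rows_in - rows_out.

Thinning enforces a minimum pairwise distance by iteratively deleting the
record with the most neighbours inside the radius (ties broken uniformly at
random) and keeps the best of ``reps`` randomised runs — the published
spThin heuristic.

Pseudo-absences are drawn at cell resolution, without replacement,
probability proportional to a sampling-bias weight, restricted to regions
holding more than a minimum number of presence records, and never from a
presence cell.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seed import derive_seed
from .grids import ClimateStack
from .synthetic import BiasLayer, ReferencePoints

__all__ = [
    "PrepConfig",
    "PseudoAbsenceSet",
    "clean_records",
    "snap_to_grid",
    "thin_records",
    "draw_pseudo_absences",
    "quadrant_regions",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

REQUIRED_COLUMNS = (
    "species",
    "decimalLongitude",
    "decimalLatitude",
    "year",
    "coordinateUncertaintyInMeters",
    "basisOfRecord",
)

FILTER_ORDER = (
    "basis_of_record",
    "year",
    "uncertainty",
    "equal_lon_lat",
    "zero_zero",
    "capital",
    "centroid",
    "institution",
    "hq",
)


@dataclass
class PrepConfig:
    """Cleaning radii/cutoffs and background-sampling rules.

    Distance semantics: with ``metric="haversine"`` coordinates are
    lon/lat degrees, the km/m radii use great-circle distance (mean Earth
    radius 6371.0088 km) and the degree radii use planar degrees.  With
    ``metric="euclidean"`` (planar synthetic domains) coordinate units are
    read as kilometres, so km radii apply unchanged and the metre radius is
    divided by 1000; degree radii are read in coordinate units.
    """

    year_cutoff: int = 1981
    max_uncertainty: float = 1000.0  # metres
    zero_zero_radius: float = 0.5  # degrees
    capital_radius_km: float = 10.0
    centroid_radius_km: float = 1.0
    institution_radius_m: float = 100.0
    hq_radius_deg: float = 0.5
    reference_points: ReferencePoints = field(default_factory=ReferencePoints)
    disallowed_basis: tuple[str, ...] = ("FOSSIL_SPECIMEN", "MACHINE_OBSERVATION")
    thin_distance: float = 10.0  # km
    thin_reps: int = 20
    min_records_per_region: int = 10
    pa_floor: int = 100
    pa_draws: int = 5
    metric: str = "haversine"

    def __post_init__(self) -> None:
        for name in (
            "max_uncertainty",
            "zero_zero_radius",
            "capital_radius_km",
            "centroid_radius_km",
            "institution_radius_m",
            "hq_radius_deg",
            "thin_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pa_draws < 1:
            raise ValueError("pa_draws must be at least 1")
        if self.metric not in ("haversine", "euclidean"):
            raise ValueError("metric must be 'haversine' or 'euclidean'")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (
        np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2)
    )
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _dist_to_points(
    lon: np.ndarray,
    lat: np.ndarray,
    points: Sequence[tuple[float, float]],
    metric: str,
) -> np.ndarray:
    """Distance from every record to its nearest reference point."""
    if not points:
        return np.full(len(lon), np.inf)
    best = np.full(len(lon), np.inf)
    for plon, plat in points:
        if metric == "haversine":
            d = haversine_km(lon, lat, plon, plat)
        else:
            d = np.hypot(lon - plon, lat - plat)
        best = np.minimum(best, d)
    return best


def _check_schema(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"occurrence table is missing required column {col!r}")


def clean_records(
    table: pd.DataFrame, cfg: PrepConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-quality filters; return (kept, audit counts).

    Filters run in :data:`FILTER_ORDER`; the audit maps filter name to the
    number of records it removed.  Permuting input rows changes neither the
    retained set nor the audit totals (every filter is row-independent).
    """
    _check_schema(table)
    audit = {name: 0 for name in FILTER_ORDER}
    if len(table) == 0:
        return table.copy(), audit

    kept = table.copy()
    metric = cfg.metric
    refs = cfg.reference_points

    def apply(name: str, bad: pd.Series) -> None:
        nonlocal kept
        bad = bad.fillna(False).astype(bool)
        audit[name] = int(bad.sum())
        kept = kept.loc[~bad]

    apply("basis_of_record", kept["basisOfRecord"].isin(cfg.disallowed_basis))
    apply("year", kept["year"] < cfg.year_cutoff)
    apply("uncertainty", kept["coordinateUncertaintyInMeters"] > cfg.max_uncertainty)
    apply("equal_lon_lat", kept["decimalLongitude"] == kept["decimalLatitude"])

    lon = kept["decimalLongitude"].to_numpy(float)
    lat = kept["decimalLatitude"].to_numpy(float)
    zz = np.hypot(lon, lat)  # degree distance to (0, 0)
    apply("zero_zero", pd.Series(zz < cfg.zero_zero_radius, index=kept.index))

    def near(points, radius):
        lon = kept["decimalLongitude"].to_numpy(float)
        lat = kept["decimalLatitude"].to_numpy(float)
        d = _dist_to_points(lon, lat, points, metric)
        return pd.Series(d < radius, index=kept.index)

    apply("capital", near(refs.capitals, cfg.capital_radius_km))
    apply("centroid", near(refs.centroids, cfg.centroid_radius_km))
    # institution radius is specified in metres; planar coordinate units
    # are km-like, so the conversion applies in both metrics
    apply(
        "institution",
        near(refs.institutions, cfg.institution_radius_m / 1000.0),
    )
    # HQ radius is specified in degrees regardless of metric
    lon = kept["decimalLongitude"].to_numpy(float)
    lat = kept["decimalLatitude"].to_numpy(float)
    d = _dist_to_points(lon, lat, refs.hq, "euclidean")
    apply("hq", pd.Series(d < cfg.hq_radius_deg, index=kept.index))

    return kept.reset_index(drop=True), audit


def snap_to_grid(
    table: pd.DataFrame, stack: ClimateStack
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Aggregate records to grid cells and centre their coordinates.

    At most one record per species per cell survives; output coordinates are
    exact cell centres.  Aggregation keeps the minimum year and minimum
    coordinate uncertainty so the result is invariant to input row order.
    Records outside the stack extent are dropped and counted in the audit.
    """
    _check_schema(table)
    audit = {"outside_extent": 0, "aggregated": 0}
    if len(table) == 0:
        return table.copy(), audit
    rows, cols, inside = stack.geometry.cell_of(
        table["decimalLongitude"].to_numpy(float),
        table["decimalLatitude"].to_numpy(float),
    )
    audit["outside_extent"] = int((~inside).sum())
    t = table.loc[inside].copy()
    t["row"] = rows[inside]
    t["col"] = cols[inside]
    grouped = (
        t.groupby(["species", "row", "col"], as_index=False)
        .agg(
            year=("year", "min"),
            coordinateUncertaintyInMeters=("coordinateUncertaintyInMeters", "min"),
            basisOfRecord=("basisOfRecord", "min"),
        )
        .sort_values(["species", "row", "col"], kind="mergesort")
        .reset_index(drop=True)
    )
    audit["aggregated"] = int(inside.sum()) - len(grouped)
    x, y = stack.geometry.center_of(
        grouped["row"].to_numpy(), grouped["col"].to_numpy()
    )
    grouped["decimalLongitude"] = x
    grouped["decimalLatitude"] = y
    cols_out = [
        "species",
        "decimalLongitude",
        "decimalLatitude",
        "year",
        "coordinateUncertaintyInMeters",
        "basisOfRecord",
        "row",
        "col",
    ]
    return grouped[cols_out], audit


def _pairwise_distances(lon, lat, metric: str) -> np.ndarray:
    if metric == "haversine":
        return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    dx = lon[:, None] - lon[None, :]
    dy = lat[:, None] - lat[None, :]
    return np.hypot(dx, dy)


def thin_records(
    table: pd.DataFrame,
    thin_distance: float,
    reps: int = 20,
    seed: int = 0,
    metric: str = "haversine",
) -> pd.DataFrame:
    """Enforce a minimum pairwise distance between retained records.

    Iteratively deletes the record with the most neighbours within
    ``thin_distance`` (ties broken uniformly at random) until no pair
    violates the constraint; among ``reps`` randomised runs the one
    retaining the most records is returned.  Identical seed, identical
    output.  Call with a single species at a time.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    _check_schema(table)
    n = len(table)
    if n <= 1:
        return table.copy()
    if table["species"].nunique() > 1:
        raise ValueError("thin_records expects a single species per call")

    lon = table["decimalLongitude"].to_numpy(float)
    lat = table["decimalLatitude"].to_numpy(float)
    dist = _pairwise_distances(lon, lat, metric)
    neighbour = dist < thin_distance
    np.fill_diagonal(neighbour, False)
    if not neighbour.any():
        return table.copy()

    root = derive_seed(seed, "thin", n)
    best_keep: np.ndarray | None = None
    for rep in range(reps):
        rng = np.random.default_rng(derive_seed(root, rep))
        adj = neighbour.copy()
        alive = np.ones(n, dtype=bool)
        counts = adj.sum(axis=1)
        order: list[int] = []  # deletion order, for the re-add pass
        while True:
            worst = counts.max()
            if worst == 0:
                break
            candidates = np.nonzero(alive & (counts == worst))[0]
            drop = int(rng.choice(candidates))
            alive[drop] = False
            order.append(drop)
            hit = np.nonzero(adj[drop])[0]
            counts[hit] -= 1
            counts[drop] = 0
            adj[drop, :] = False
            adj[:, drop] = False
        # maximalise: a deleted record whose neighbours were all deleted
        # later can rejoin without violating the distance constraint
        for idx in order:
            if not neighbour[idx][alive].any():
                alive[idx] = True
        if best_keep is None or alive.sum() > best_keep.sum():
            best_keep = alive
    assert best_keep is not None
    return table.loc[best_keep].reset_index(drop=True)


def max_retained_bruteforce(
    table: pd.DataFrame, thin_distance: float, metric: str = "haversine"
) -> int:
    """Exhaustive-subset oracle for thinning: the maximum number of records
    that can be retained with all pairwise distances >= thin_distance.

    Exponential in n; intended for n <= ~15 in tests.
    """
    n = len(table)
    lon = table["decimalLongitude"].to_numpy(float)
    lat = table["decimalLatitude"].to_numpy(float)
    dist = _pairwise_distances(lon, lat, metric)
    conflict = dist < thin_distance
    np.fill_diagonal(conflict, False)
    best = 0
    for size in range(n, 0, -1):
        if size <= best:
            break
        for subset in itertools.combinations(range(n), size):
            idx = np.array(subset)
            if not conflict[np.ix_(idx, idx)].any():
                best = size
                break
        if best:
            break
    return best


def quadrant_regions(stack: ClimateStack) -> np.ndarray:
    """Region map splitting a synthetic domain into its four grid quadrants.

    Stands in for the continents of a global analysis; returns an integer
    array (0..3) aligned with the stack grid.
    """
    n_rows, n_cols = stack.shape
    rows = (np.arange(n_rows) >= n_rows / 2).astype(int)
    cols = (np.arange(n_cols) >= n_cols / 2).astype(int)
    return rows[:, None] * 2 + cols[None, :]


@dataclass
class PseudoAbsenceSet:
    """One background draw: cells with centre coordinates."""

    draw_index: int
    cells: pd.DataFrame  # columns row, col, decimalLongitude, decimalLatitude

    def __len__(self) -> int:
        return len(self.cells)


class InsufficientBackgroundError(ValueError):
    """Raised when the candidate pool is smaller than the requested draw."""


def draw_pseudo_absences(
    presences: pd.DataFrame,
    stack: ClimateStack,
    bias: BiasLayer,
    regions: np.ndarray | None,
    cfg: PrepConfig,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Weighted background draws matching the presence count.

    Per draw, the number of pseudo-absences equals the number of thinned
    presences, floored at ``cfg.pa_floor`` (100 by default) for sparse
    species.  Candidate cells are restricted to regions holding strictly
    more than ``cfg.min_records_per_region`` presence records, exclude the
    presence cells themselves, and are sampled without replacement with
    probability proportional to the bias weight.  ``cfg.pa_draws``
    independent sets are returned.
    """
    _check_schema(presences)
    if len(presences) == 0:
        raise ValueError("no presence records supplied")
    rows, cols, inside = stack.geometry.cell_of(
        presences["decimalLongitude"].to_numpy(float),
        presences["decimalLatitude"].to_numpy(float),
    )
    if not inside.all():
        raise ValueError("presence records fall outside the stack extent")
    if regions is None:
        regions = np.zeros(stack.shape, dtype=int)
    regions = np.asarray(regions)
    if regions.shape != stack.shape:
        raise ValueError("region map shape does not match stack geometry")

    n_presence = len(presences)
    n_pa = n_presence if n_presence >= cfg.pa_floor else cfg.pa_floor

    pres_regions = regions[rows, cols]
    region_counts = pd.Series(pres_regions).value_counts()
    eligible_regions = set(
        region_counts[region_counts > cfg.min_records_per_region].index
    )
    if not eligible_regions:
        raise InsufficientBackgroundError(
            "no region holds more than "
            f"{cfg.min_records_per_region} presence records"
        )

    land = stack.land_mask()
    candidate_mask = land & np.isin(regions, list(eligible_regions))
    candidate_mask[rows, cols] = False  # never draw an absence from a presence cell
    cand_rows, cand_cols = np.nonzero(candidate_mask)
    if len(cand_rows) < n_pa:
        raise InsufficientBackgroundError(
            f"candidate pool ({len(cand_rows)} cells) smaller than the "
            f"requested {n_pa} pseudo-absences"
        )
    weights = bias.weights[cand_rows, cand_cols]
    wsum = weights.sum()
    if wsum <= 0:
        raise InsufficientBackgroundError(
            "bias weights are zero over the whole candidate pool"
        )
    p = weights / wsum
    if int((p > 0).sum()) < n_pa:
        raise InsufficientBackgroundError(
            "fewer positively weighted candidate cells than pseudo-absences"
        )

    sets = []
    for draw in range(cfg.pa_draws):
        rng = np.random.default_rng(derive_seed(seed, "pa_draw", draw))
        pick = rng.choice(len(cand_rows), size=n_pa, replace=False, p=p)
        r, c = cand_rows[pick], cand_cols[pick]
        x, y = stack.geometry.center_of(r, c)
        cells = pd.DataFrame(
            {"row": r, "col": c, "decimalLongitude": x, "decimalLatitude": y}
        )
        sets.append(PseudoAbsenceSet(draw_index=draw, cells=cells))
    return sets
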