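"""Range-interval climatic niche overlap and log-response-ratio pairs.

Per-variable overlap is the percentage of a species' occurrence records
whose value of a climate variable falls (inclusively) within the island's
min-max range for that variable.  The cumulative overlap of a predictor set
weights each variable's overlap by its (normalised) importance in the
corresponding SDM.  The predictor set with the highest mean cumulative
overlap across species and islands serves as the baseline; every other set
is compared to it by log-response ratios

    LRR = ln((X2 + c) / (X1 + c)),   c = 0.00001,

for both the suitable-cell proportion and the cumulative overlap (as a
proportion).  The small constant guards the zero-proportion case; it also
makes the LRR exactly antisymmetric in its arguments.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ClimateStack

__all__ = [
    "ClimaticRange",
    "island_climate_range",
    "variable_overlap",
    "weighted_cumulative_overlap",
    "select_baseline",
    "lrr",
    "pair_lrrs",
    "LRR_CONSTANT",
]

logger = logging.getLogger(__name__)

LRR_CONSTANT = 0.00001


@dataclass
class ClimaticRange:
    """Per-variable (min, max) over an island's land cells."""

    island: str
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{var!r}: min {lo} exceeds max {hi}")

    @classmethod
    def combine(cls, ranges: Sequence["ClimaticRange"], island: str) -> "ClimaticRange":
        """Union of ranges (islands pooled into one archipelago group)."""
        if not ranges:
            raise ValueError("no ranges to combine")
        variables = set(ranges[0].bounds)
        for r in ranges[1:]:
            variables &= set(r.bounds)
        bounds = {
            v: (
                min(r.bounds[v][0] for r in ranges),
                max(r.bounds[v][1] for r in ranges),
            )
            for v in sorted(variables)
        }
        return cls(island=island, bounds=bounds)


def island_climate_range(island_stack: ClimateStack) -> ClimaticRange:
    """Min/max of every variable over unmasked, finite island cells."""
    table = island_stack.land_table()
    if len(table) == 0:
        raise ValueError(f"island {island_stack.name!r} has an empty land mask")
    bounds = {
        var: (float(table[var].min()), float(table[var].max()))
        for var in island_stack.variables
    }
    return ClimaticRange(island=island_stack.name, bounds=bounds)


def variable_overlap(species_values, value_range: tuple[float, float]) -> float:
    """Percentage of record values inside [min, max], bounds inclusive."""
    values = np.asarray(species_values, dtype=float)
    if values.size == 0:
        raise ValueError("variable_overlap requires at least one record")
    lo, hi = value_range
    inside = (values >= lo) & (values <= hi)
    return 100.0 * inside.sum() / values.size


def weighted_cumulative_overlap(
    overlaps: Mapping[str, float], importances: Mapping[str, float]
) -> float:
    """Importance-weighted sum of per-variable overlaps, on the 0-100 scale.

    Weights are the variable importances normalised to sum to one (so the
    result is a convex combination of the per-variable overlaps); with an
    all-zero importance vector the variables are weighted equally.
    """
    if set(overlaps) != set(importances):
        raise ValueError("overlaps and importances must cover the same variables")
    variables = list(overlaps)
    w = np.array([importances[v] for v in variables], dtype=float)
    if np.any(w < 0):
        raise ValueError("importances must be non-negative")
    total = w.sum()
    if total == 0:
        w = np.full(len(variables), 1.0 / len(variables))
    else:
        w = w / total
    o = np.array([overlaps[v] for v in variables], dtype=float)
    return float(np.dot(o, w))


def select_baseline(omega_table: pd.DataFrame) -> str:
    """Predictor set with the highest mean cumulative overlap.

    ``omega_table`` has columns predictor_set, species, island, omega; the
    mean is unweighted over species x island rows.  Ties break toward the
    lexicographically first set id (logged).
    """
    if len(omega_table) == 0:
        raise ValueError("empty cumulative-overlap table")
    means = (
        omega_table.groupby("predictor_set")["omega"].mean().sort_index()
    )
    best = means.max()
    winners = means[means == best].index.tolist()
    if len(winners) > 1:
        logger.info(
            "baseline tie between %s (mean omega %.6g); choosing %s",
            winners,
            best,
            winners[0],
        )
    return winners[0]


def lrr(x1: float, x2: float, c: float = LRR_CONSTANT) -> float:
    """ln(1 + (X2' - X1')/X1') = ln(X2'/X1') with X' = X + c.

    Both arguments are proportions in [0, 1]; ``c > 0`` keeps the ratio
    finite at zero and makes the measure exactly antisymmetric:
    lrr(a, b) == -lrr(b, a).
    """
    for name, x in (("x1", x1), ("x2", x2)):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"{name}={x} outside [0, 1]")
    if c <= 0:
        raise ValueError("c must be positive")
    return math.log((x2 + c) / (x1 + c))


def pair_lrrs(
    suitability: pd.DataFrame,
    omega_table: pd.DataFrame,
    baseline: str,
    c: float = LRR_CONSTANT,
) -> pd.DataFrame:
    """One LRR pair per species x island x non-baseline predictor set.

    ``suitability`` needs columns species, island, predictor_set,
    fraction_suitable; ``omega_table`` needs species, island,
    predictor_set, omega (percent).  Rows where either side is missing
    (failed ensemble) are dropped; the count of dropped rows is attached as
    ``DataFrame.attrs["n_dropped"]``.
    """
    if baseline not in set(suitability["predictor_set"]):
        raise ValueError(f"baseline {baseline!r} absent from the suitability table")
    if baseline not in set(omega_table["predictor_set"]):
        raise ValueError(f"baseline {baseline!r} absent from the overlap table")

    suit = suitability[["species", "island", "predictor_set", "fraction_suitable"]]
    om = omega_table[["species", "island", "predictor_set", "omega"]].copy()
    om["omega"] = om["omega"] / 100.0  # percent -> proportion

    base_suit = suit[suit["predictor_set"] == baseline].rename(
        columns={"fraction_suitable": "x1"}
    )[["species", "island", "x1"]]
    base_om = om[om["predictor_set"] == baseline].rename(
        columns={"omega": "omega1"}
    )[["species", "island", "omega1"]]
    comp = suit[suit["predictor_set"] != baseline].rename(
        columns={"fraction_suitable": "x2"}
    )
    comp = comp.merge(
        om[om["predictor_set"] != baseline].rename(columns={"omega": "omega2"}),
        on=["species", "island", "predictor_set"],
        how="outer",
    )
    merged = comp.merge(base_suit, on=["species", "island"], how="left").merge(
        base_om, on=["species", "island"], how="left"
    )
    n_before = len(merged)
    merged = merged.dropna(subset=["x1", "x2", "omega1", "omega2"]).reset_index(
        drop=True
    )
    merged["baseline"] = baseline
    merged["lrr_suitability"] = [
        lrr(a, b, c) for a, b in zip(merged["x1"], merged["x2"])
    ]
    merged["lrr_overlap"] = [
        lrr(a, b, c) for a, b in zip(merged["omega1"], merged["omega2"])
    ]
    out = merged[
        [
            "species",
            "island",
            "predictor_set",
            "baseline",
            "x1",
            "x2",
            "lrr_suitability",
            "omega1",
            "omega2",
            "lrr_overlap",
        ]
    ].sort_values(["species", "island", "predictor_set"], kind="mergesort")
    out = out.reset_index(drop=True)
    out.attrs["n_dropped"] = n_before - len(out)
    return out
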