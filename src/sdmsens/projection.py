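"""Binary projection of ensembles onto island rasters and island summaries.

An ensemble's continuous scores are binarised at its maxTSS threshold cell
by cell over an island's land surface; the per-island summary is the
fraction of land cells projected suitable.  An island counts as predicted
suitable for a species when at least one cell is suitable.  Island-level
confusion statistics compare those predictions with an independent record
set over the pool of successfully modelled species.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ClimateStack
from .sdm import EnsembleModel, Evaluation

__all__ = [
    "SuitabilityGrid",
    "project_binary",
    "island_presence",
    "confusion_by_island",
    "suitability_matrix",
]


@dataclass
class SuitabilityGrid:
    """Binary suitability of one species x island x predictor set."""

    island: str
    species: str
    predictor_set: str
    binary: np.ndarray  # float: 1 suitable, 0 unsuitable, NaN excluded
    n_land_cells: int
    n_suitable: int

    @property
    def fraction_suitable(self) -> float:
        return self.n_suitable / self.n_land_cells

    def __post_init__(self) -> None:
        if not (0 <= self.n_suitable <= self.n_land_cells):
            raise ValueError("n_suitable must lie in [0, n_land_cells]")


def project_binary(
    ensemble: EnsembleModel,
    island_stack: ClimateStack,
    species: str = "",
) -> SuitabilityGrid:
    """Evaluate the ensemble on every island land cell and binarise.

    Cells missing any predictor value (masked or non-finite) are excluded
    from the denominator rather than counted unsuitable.  Raises naming the
    variable if the island stack lacks a predictor band.
    """
    if ensemble.failed:
        raise RuntimeError(
            f"cannot project failed ensemble for {ensemble.predictor_set.id!r}"
        )
    for var in ensemble.predictor_set.variables:
        if var not in island_stack.layers:
            raise KeyError(
                f"island stack {island_stack.name!r} lacks variable {var!r}"
            )
    cells = island_stack.land_table(ensemble.predictor_set.variables)
    if len(cells) == 0:
        raise ValueError(f"island {island_stack.name!r} has no usable land cells")
    scores = ensemble.predict(cells)
    suitable = scores >= ensemble.binarisation_threshold
    binary = np.full(island_stack.shape, np.nan)
    binary[cells["row"].to_numpy(), cells["col"].to_numpy()] = suitable.astype(float)
    return SuitabilityGrid(
        island=island_stack.name,
        species=species,
        predictor_set=ensemble.predictor_set.id,
        binary=binary,
        n_land_cells=len(cells),
        n_suitable=int(suitable.sum()),
    )


def island_presence(grid: SuitabilityGrid) -> bool:
    """Predicted present iff at least one island cell is suitable."""
    return grid.n_suitable >= 1


def confusion_by_island(
    predictions: Mapping[str, bool],
    recorded_species: Iterable[str],
    pool: Sequence[str],
) -> Evaluation | None:
    """Island-level confusion of predicted vs recorded species.

    ``pool`` is the candidate set (all successfully modelled species); true
    negatives come from pool minus the recorded set.  Returns None when the
    recorded set is empty on this island (sensitivity undefined).
    """
    pool = list(pool)
    recorded = set(recorded_species) & set(pool)
    absent = [s for s in pool if s not in recorded]
    if not recorded:
        return None
    tp = sum(1 for s in recorded if predictions.get(s, False))
    fn = len(recorded) - tp
    fp = sum(1 for s in absent if predictions.get(s, False))
    tn = len(absent) - fp
    if not absent:
        return None  # specificity undefined
    return Evaluation(sensitivity=tp / (tp + fn), specificity=tn / (tn + fp))


def suitability_matrix(
    grids: Iterable[SuitabilityGrid],
    failed: Iterable[tuple[str, str, str]] = (),
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate species x island x predictor set suitability.

    ``failed`` lists (species, island, predictor_set) combinations whose
    ensemble failed; they appear as missing values, never as zero.  When a
    ``groups`` map (island -> group id) is given, islands of a group are
    pooled by summing cell counts before the fraction is formed.
    """
    rows = [
        {
            "species": g.species,
            "island": g.island,
            "predictor_set": g.predictor_set,
            "n_land_cells": g.n_land_cells,
            "n_suitable": g.n_suitable,
            "fraction_suitable": g.fraction_suitable,
        }
        for g in grids
    ]
    for species, island, pset in failed:
        rows.append(
            {
                "species": species,
                "island": island,
                "predictor_set": pset,
                "n_land_cells": np.nan,
                "n_suitable": np.nan,
                "fraction_suitable": np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if groups:
        out["island"] = out["island"].map(lambda i: groups.get(i, i))
        out = (
            out.groupby(["species", "island", "predictor_set"], as_index=False)
            .agg(
                n_land_cells=("n_land_cells", "sum"),
                n_suitable=("n_suitable", "sum"),
            )
        )
        out["fraction_suitable"] = out["n_suitable"] / out["n_land_cells"]
    return out.sort_values(
        ["species", "island", "predictor_set"], kind="mergesort"
    ).reset_index(drop=True)
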