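"""Multi-variable climate grids on a shared rectilinear geometry.

A :class:`ClimateStack` holds one 2-D array per bioclimatic variable plus an
optional land mask, all on the same grid.  Geometry follows the usual raster
convention of a regular cell lattice; coordinates refer to cell centres.
Synthetic domains are planar by default (coordinate units are interpreted as
kilometres); geographic stacks carry lon/lat degrees and use great-circle
distances downstream.

On disk a stack is one ESRI ASCII grid (``.asc``) per variable plus a JSON
sidecar with the domain name, variable list, geometry and an optional echo of
the generating configuration.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GridGeometry", "ClimateStack"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular cell lattice; row 0 is the southern-/bottom-most row."""

    n_rows: int
    n_cols: int
    x_min: float = 0.0
    y_min: float = 0.0
    cell_size: float = 1.0
    geographic: bool = False

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_coords(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_coords(self) -> np.ndarray:
        return self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def cell_of(self, x, y):
        """Map coordinates to (row, col); returns (rows, cols, inside_mask)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.x_min) / self.cell_size).astype(int)
        rows = np.floor((y - self.y_min) / self.cell_size).astype(int)
        inside = (
            (cols >= 0) & (cols < self.n_cols) & (rows >= 0) & (rows < self.n_rows)
        )
        return rows, cols, inside

    def center_of(self, rows, cols):
        """Cell-centre coordinates for (row, col) indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.x_min + (cols + 0.5) * self.cell_size
        y = self.y_min + (rows + 0.5) * self.cell_size
        return x, y

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "x_min": self.x_min,
            "y_min": self.y_min,
            "cell_size": self.cell_size,
            "geographic": self.geographic,
        }


@dataclass
class ClimateStack:
    """Named set of co-registered single-variable rasters.

    Parameters
    ----------
    name
        Domain label (e.g. ``"calibration"`` or an island name).
    geometry
        Shared :class:`GridGeometry`.
    layers
        Mapping variable id -> 2-D float array of shape (n_rows, n_cols).
    mask
        Boolean land mask, ``True`` where cells count as land.  Defaults to
        all-land (synthetic islands are full rectangles unless a mask is
        supplied).
    config_echo
        Optional JSON-serialisable echo of the generating configuration.
    """

    name: str
    geometry: GridGeometry
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    config_echo: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        if not self.layers:
            raise ValueError("a ClimateStack needs at least one variable layer")
        clean = {}
        for var, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"layer {var!r} has shape {arr.shape}, expected {shape}"
                )
            clean[var] = arr
        self.layers = clean
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape does not match geometry")

    # -- basic views ----------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.geometry.n_rows, self.geometry.n_cols)

    @property
    def n_land_cells(self) -> int:
        return int(self.land_mask().sum())

    def land_mask(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Land cells with finite values in every requested variable."""
        variables = self.variables if variables is None else list(variables)
        ok = self.mask.copy()
        for var in variables:
            ok &= np.isfinite(self.layers[var])
        return ok

    def land_table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """One row per land cell: row, col, x, y plus variable columns."""
        variables = self.variables if variables is None else list(variables)
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack {self.name!r}: {missing}")
        ok = self.land_mask(variables)
        rows, cols = np.nonzero(ok)
        x, y = self.geometry.center_of(rows, cols)
        out = pd.DataFrame({"row": rows, "col": cols, "x": x, "y": y})
        for var in variables:
            out[var] = self.layers[var][rows, cols]
        return out

    def values_at(
        self, x, y, variables: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Variable values at the cells containing (x, y); NaN outside."""
        variables = self.variables if variables is None else list(variables)
        rows, cols, inside = self.geometry.cell_of(x, y)
        out = pd.DataFrame(index=np.arange(len(np.atleast_1d(rows))))
        r = np.where(inside, rows, 0)
        c = np.where(inside, cols, 0)
        for var in variables:
            vals = self.layers[var][r, c].astype(float)
            vals[~inside] = np.nan
            out[var] = vals
        return out

    # -- I/O -------------------------------------------------------------
    def to_dir(self, path: str | Path) -> Path:
        """Write one .asc per variable (plus mask) and a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for var, arr in self.layers.items():
            _write_asc(path / f"{var}.asc", arr, self.geometry)
        _write_asc(path / "__mask__.asc", self.mask.astype(float), self.geometry)
        sidecar = {
            "name": self.name,
            "variables": self.variables,
            "geometry": self.geometry.to_dict(),
            "config_echo": self.config_echo,
        }
        (path / "stack.json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClimateStack":
        path = Path(path)
        sidecar = json.loads((path / "stack.json").read_text())
        geometry = GridGeometry(**sidecar["geometry"])
        layers = {
            var: _read_asc(path / f"{var}.asc") for var in sidecar["variables"]
        }
        mask_file = path / "__mask__.asc"
        mask = _read_asc(mask_file).astype(bool) if mask_file.exists() else None
        return cls(
            name=sidecar["name"],
            geometry=geometry,
            layers=layers,
            mask=mask,
            config_echo=sidecar.get("config_echo"),
        )


_NODATA = -9999.0


def _write_asc(path: Path, arr: np.ndarray, geom: GridGeometry) -> None:
    data = np.where(np.isfinite(arr), arr, _NODATA)
    header = (
        f"ncols {geom.n_cols}\n"
        f"nrows {geom.n_rows}\n"
        f"xllcorner {geom.x_min!r}\n"
        f"yllcorner {geom.y_min!r}\n"
        f"cellsize {geom.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids store the top row first
        np.savetxt(fh, np.flipud(data), fmt="%.10g")


def _read_asc(path: Path) -> np.ndarray:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.flipud(np.atleast_2d(data))
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data


def stacks_compatible(a: ClimateStack, b: ClimateStack) -> bool:
    """True when two stacks share geometry (not necessarily variables)."""
    return a.geometry == b.geometry
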