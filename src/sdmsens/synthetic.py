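"""Synthetic climate domains, virtual species and biased occurrence sampling.

The generator emulates the data layout of a global SDM study — multi-variable
bioclimatic raster stacks, presence-only occurrence tables with the usual
quality problems, and a sampling-bias surface — with fully known ground truth
so every downstream stage can be tested without external downloads.

Random fields are linear mixtures of spatially smoothed independent Gaussian
noise fields.  After smoothing, the fields are empirically whitened
(centred and decorrelated) before mixing with a square root of the target
correlation matrix, so the realised inter-variable correlation matrix, the
per-variable means and the standard deviations match the configuration
*exactly* at any grid size rather than only asymptotically.  A projection
domain can decouple chosen variable pairs (novel correlation structure) and
shift variables outside the calibration range (novel values) — the two faces
of a non-analogue climate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seed import derive_seed
from .grids import ClimateStack, GridGeometry

__all__ = [
    "DomainConfig",
    "GaussianResponse",
    "LogisticResponse",
    "NicheSpec",
    "BiasLayer",
    "ReferencePoints",
    "UnsampleableSpeciesError",
    "generate_climate_domain",
    "make_projection_domain",
    "sample_occurrences",
    "uniform_bias",
    "gradient_bias",
    "DIRTY_CATEGORIES",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------
@dataclass
class DomainConfig:
    """Recipe for one synthetic climate domain.

    ``correlation`` is the target inter-variable correlation matrix
    (symmetric, unit diagonal, positive semi-definite); ``mean`` and ``sd``
    are per-variable location and scale in variable units.
    ``spatial_smoothness`` is the Gaussian kernel width (in cells) of the
    underlying random fields, i.e. the correlation length of the spatial
    pattern.  ``range_shift`` adds a per-variable offset (used for
    projection domains whose values exceed the calibration range).
    """

    name: str
    n_rows: int
    n_cols: int
    variables: tuple[str, ...]
    correlation: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    cell_size: float = 1.0
    x_min: float = 0.0
    y_min: float = 0.0
    spatial_smoothness: float = 3.0
    geographic: bool = False
    range_shift: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        k = len(self.variables)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.correlation.shape != (k, k):
            raise ValueError("correlation matrix shape must match variables")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if self.mean.shape != (k,) or self.sd.shape != (k,):
            raise ValueError("mean/sd must have one entry per variable")
        if np.any(self.sd <= 0):
            raise ValueError("all sd entries must be positive")
        if self.n_rows * self.n_cols < 1:
            raise ValueError("domain must contain at least one cell")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            x_min=self.x_min,
            y_min=self.y_min,
            cell_size=self.cell_size,
            geographic=self.geographic,
        )


@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped suitability: exp(-0.5 ((v - optimum)/breadth)^2)."""

    optimum: float
    breadth: float

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        z = (np.asarray(values, dtype=float) - self.optimum) / self.breadth
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoidal suitability; direction +1 rises with the variable."""

    midpoint: float
    slope: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        z = self.direction * (np.asarray(values, dtype=float) - self.midpoint)
        return 1.0 / (1.0 + np.exp(-self.slope * z))


@dataclass
class NicheSpec:
    """A virtual species: known response curves over climate variables.

    ``combination`` is how per-variable suitabilities combine: ``"product"``
    (interactive limitation) or ``"minimum"`` (Liebig-style limiting factor).
    ``prevalence_target`` is carried for bookkeeping; occurrence sampling
    normalises suitability into a probability mass, so a global rescale of
    suitability has no effect on where records land.
    """

    species_id: str
    responses: dict[str, GaussianResponse | LogisticResponse]
    combination: str = "product"
    prevalence_target: float = 1.0

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("a niche needs at least one response curve")
        if self.combination not in ("product", "minimum"):
            raise ValueError("combination must be 'product' or 'minimum'")
        if not (0 < self.prevalence_target <= 1):
            raise ValueError("prevalence_target must be in (0, 1]")

    def suitability(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Combined suitability in [0, 1] from per-variable value arrays."""
        parts = []
        for var, resp in self.responses.items():
            if var not in values:
                raise KeyError(f"niche variable {var!r} missing from input")
            parts.append(resp(np.asarray(values[var], dtype=float)))
        stackv = np.stack(parts)
        if self.combination == "product":
            return np.prod(stackv, axis=0)
        return np.min(stackv, axis=0)

    def suitability_on(self, stack: ClimateStack) -> np.ndarray:
        return self.suitability({v: stack.layers[v] for v in self.responses})


@dataclass
class BiasLayer:
    """Non-negative sampling-effort weights on the calibration geometry."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("bias weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one bias weight must be positive")


def uniform_bias(stack: ClimateStack) -> BiasLayer:
    return BiasLayer(np.ones(stack.shape))


def gradient_bias(stack: ClimateStack, axis: int = 1, strength: float = 4.0) -> BiasLayer:
    """East-west (axis=1) or south-north (axis=0) effort gradient.

    Emulates the over-representation of well-surveyed regions in global
    occurrence archives; weight ranges from 1 to ``strength``.
    """
    n = stack.shape[axis]
    ramp = 1.0 + (strength - 1.0) * np.arange(n) / max(n - 1, 1)
    if axis == 1:
        w = np.tile(ramp, (stack.shape[0], 1))
    else:
        w = np.tile(ramp[:, None], (1, stack.shape[1]))
    return BiasLayer(w)


# ---------------------------------------------------------------------------
# random-field machinery
# ---------------------------------------------------------------------------
def _correlation_sqrt(corr: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD correlation matrix.

    Uses the eigendecomposition so singular matrices (e.g. a perfectly
    correlated pair) are handled; rejects non-PSD input naming the offending
    eigenvalue.
    """
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        raise ValueError(
            "correlation matrix is not positive semi-definite: "
            f"smallest eigenvalue {eigvals.min():.6g}"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvecs @ np.diag(np.sqrt(eigvals)) @ eigvecs.T


def _smoothed_white_fields(
    k: int, n_rows: int, n_cols: int, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """k independent smoothed fields, empirically whitened.

    Returns array (k, n_cells) with exactly zero mean, unit variance and
    zero pairwise correlation (sample moments), while retaining the spatial
    autocorrelation induced by the Gaussian smoothing kernel.
    """
    n_cells = n_rows * n_cols
    fields = rng.standard_normal((k, n_rows, n_cols))
    if smoothness > 0:
        for i in range(k):
            fields[i] = gaussian_filter(fields[i], sigma=smoothness, mode="wrap")
    flat = fields.reshape(k, n_cells)
    flat -= flat.mean(axis=1, keepdims=True)
    if n_cells > k:
        # whiten: remove sample cross-correlation so that mixing yields the
        # target correlation exactly, not just in expectation
        cov = flat @ flat.T / n_cells
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        flat = np.linalg.solve(L, flat)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    flat /= sd
    return flat


def generate_climate_domain(config: DomainConfig) -> ClimateStack:
    """Realise a :class:`ClimateStack` from a :class:`DomainConfig`.

    Deterministic: identical config (including seed) gives bit-identical
    rasters.  Realised means, sds and the inter-variable correlation matrix
    equal the configured targets up to floating-point error.
    """
    k = len(config.variables)
    sqrt_c = _correlation_sqrt(config.correlation)
    rng = np.random.default_rng(derive_seed(config.seed, "domain", config.name))
    n_cells = config.n_rows * config.n_cols
    if n_cells > k:
        white = _smoothed_white_fields(
            k, config.n_rows, config.n_cols, config.spatial_smoothness, rng
        )
    else:
        # degenerate tiny grids: exact moments are unattainable; fall back to
        # plain correlated draws
        white = rng.standard_normal((k, n_cells))
    mixed = sqrt_c @ white
    layers = {}
    for i, var in enumerate(config.variables):
        vals = config.mean[i] + config.sd[i] * mixed[i]
        vals = vals + config.range_shift.get(var, 0.0)
        layers[var] = vals.reshape(config.n_rows, config.n_cols)
    echo = {
        "variables": list(config.variables),
        "correlation": config.correlation.tolist(),
        "mean": config.mean.tolist(),
        "sd": config.sd.tolist(),
        "range_shift": dict(config.range_shift),
        "spatial_smoothness": config.spatial_smoothness,
        "seed": config.seed,
    }
    return ClimateStack(
        name=config.name, geometry=config.geometry, layers=layers, config_echo=echo
    )


def make_projection_domain(
    base: DomainConfig,
    decouple: Iterable[tuple[str, str]] = (),
    range_shift: Mapping[str, float] | None = None,
    *,
    name: str | None = None,
    n_rows: int | None = None,
    n_cols: int | None = None,
    seed: int | None = None,
) -> ClimateStack:
    """Projection-domain stack with altered correlation structure.

    Each pair in ``decouple`` has its target correlation set to zero (the
    realised |r| is exactly 0 by construction, well under the 0.2 bound);
    per-variable variances are preserved.  ``range_shift`` offsets variables
    additively so part or all of their values leave the calibration range.
    Geometry may differ from the calibration domain via the size overrides.
    """
    decouple = list(decouple)
    range_shift = dict(range_shift or {})
    for pair in decouple:
        for v in pair:
            if v not in base.variables:
                raise ValueError(f"cannot decouple unknown variable {v!r}")
    for v in range_shift:
        if v not in base.variables:
            raise ValueError(f"cannot shift unknown variable {v!r}")

    idx = {v: i for i, v in enumerate(base.variables)}
    corr = base.correlation.copy()
    for a, b in decouple:
        corr[idx[a], idx[b]] = 0.0
        corr[idx[b], idx[a]] = 0.0
    # zeroing entries can leave the matrix slightly non-PSD; clip and restore
    # the unit diagonal
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < 0:
        corr = eigvecs @ np.diag(np.clip(eigvals, 0.0, None)) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        for a, b in decouple:
            corr[idx[a], idx[b]] = 0.0
            corr[idx[b], idx[a]] = 0.0
        corr = (corr + corr.T) / 2

    merged_shift = dict(base.range_shift)
    for v, s in range_shift.items():
        merged_shift[v] = merged_shift.get(v, 0.0) + s

    proj = replace(
        base,
        name=name if name is not None else f"{base.name}_projection",
        n_rows=n_rows if n_rows is not None else base.n_rows,
        n_cols=n_cols if n_cols is not None else base.n_cols,
        correlation=corr,
        range_shift=merged_shift,
        seed=seed if seed is not None else derive_seed(base.seed, "projection"),
    )
    return generate_climate_domain(proj)


# ---------------------------------------------------------------------------
# occurrence sampling
# ---------------------------------------------------------------------------
class UnsampleableSpeciesError(ValueError):
    """Raised when suitability x bias is zero everywhere."""


@dataclass(frozen=True)
class ReferencePoints:
    """Coordinates of the record-quality troublemakers.

    Capitals, country centroids, biodiversity institutions and the archive
    headquarters are the locations around which erroneously georeferenced
    records cluster in real occurrence archives.  Defaults are placed far
    from the synthetic domains so that clean records never fall inside any
    removal radius by accident.
    """

    capitals: tuple[tuple[float, float], ...] = ((120.0, 45.0),)
    centroids: tuple[tuple[float, float], ...] = ((130.0, -20.0),)
    institutions: tuple[tuple[float, float], ...] = ((140.0, 10.0),)
    hq: tuple[tuple[float, float], ...] = ((-30.0, 70.0),)


DIRTY_CATEGORIES = (
    "pre_cutoff_year",
    "high_uncertainty",
    "equal_lon_lat",
    "near_zero_zero",
    "near_capital",
    "near_centroid",
    "near_institution",
    "near_hq",
)

OCCURRENCE_COLUMNS = [
    "species",
    "decimalLongitude",
    "decimalLatitude",
    "year",
    "coordinateUncertaintyInMeters",
    "basisOfRecord",
    "provenance",
]


def sample_occurrences(
    species: NicheSpec,
    stack: ClimateStack,
    bias: BiasLayer,
    n_target: int,
    dirty_fraction: float = 0.0,
    seed: int = 0,
    *,
    reference_points: ReferencePoints | None = None,
    year_range: tuple[int, int] = (1990, 2020),
    year_cutoff: int = 1981,
    uncertainty_range: tuple[float, float] = (10.0, 500.0),
    max_uncertainty: float = 1000.0,
    categories: Sequence[str] = DIRTY_CATEGORIES,
) -> pd.DataFrame:
    """Draw a presence-only occurrence table from a virtual species.

    Cells are sampled with probability proportional to suitability x bias
    weight (with replacement — several observers can report the same cell);
    each record gets a position uniformly jittered within its cell, a clean
    year and coordinate uncertainty.  ``round(dirty_fraction * n_target)``
    records are then corrupted into one of the removable categories, with
    the category written to a ``provenance`` column (used by tests only,
    never by the pipeline).
    """
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    if not (0 <= dirty_fraction <= 1):
        raise ValueError("dirty_fraction must be in [0, 1]")
    refs = reference_points or ReferencePoints()
    rng = np.random.default_rng(derive_seed(seed, "occurrences", species.species_id))

    suit = species.suitability_on(stack)
    if np.any((suit < -1e-9) | (suit > 1 + 1e-9)):
        raise ValueError("suitability values must lie in [0, 1]")
    weight = np.clip(suit, 0.0, 1.0) * bias.weights * stack.mask
    total = weight.sum()
    if total <= 0:
        raise UnsampleableSpeciesError(
            f"species {species.species_id!r}: suitability x bias is zero "
            "everywhere on the domain"
        )
    p = (weight / total).ravel()
    flat_idx = rng.choice(weight.size, size=n_target, replace=True, p=p)
    rows, cols = np.unravel_index(flat_idx, weight.shape)
    cs = stack.geometry.cell_size
    cx, cy = stack.geometry.center_of(rows, cols)
    lon = cx + rng.uniform(-0.5, 0.5, n_target) * cs
    lat = cy + rng.uniform(-0.5, 0.5, n_target) * cs

    table = pd.DataFrame(
        {
            "species": species.species_id,
            "decimalLongitude": lon,
            "decimalLatitude": lat,
            "year": rng.integers(year_range[0], year_range[1] + 1, n_target),
            "coordinateUncertaintyInMeters": rng.uniform(
                uncertainty_range[0], uncertainty_range[1], n_target
            ),
            "basisOfRecord": "HUMAN_OBSERVATION",
            "provenance": "clean",
        }
    )

    n_dirty = int(round(dirty_fraction * n_target))
    if n_dirty:
        dirty_idx = rng.choice(n_target, size=n_dirty, replace=False)
        cats = rng.choice(list(categories), size=n_dirty, replace=True)
        for i, cat in zip(dirty_idx, cats):
            _corrupt(table, int(i), str(cat), rng, refs, year_cutoff, max_uncertainty)
    return table


def _jitter_near(
    point: tuple[float, float], radius_deg: float, rng: np.random.Generator
) -> tuple[float, float]:
    ang = rng.uniform(0, 2 * math.pi)
    r = radius_deg * math.sqrt(rng.uniform(0, 1))
    return point[0] + r * math.cos(ang), point[1] + r * math.sin(ang)


def _corrupt(
    table: pd.DataFrame,
    i: int,
    category: str,
    rng: np.random.Generator,
    refs: ReferencePoints,
    year_cutoff: int,
    max_uncertainty: float,
) -> None:
    if category == "pre_cutoff_year":
        table.loc[i, "year"] = int(rng.integers(1900, year_cutoff))
    elif category == "high_uncertainty":
        table.loc[i, "coordinateUncertaintyInMeters"] = float(
            rng.uniform(2 * max_uncertainty, 20 * max_uncertainty)
        )
    elif category == "equal_lon_lat":
        table.loc[i, "decimalLatitude"] = table.loc[i, "decimalLongitude"]
    elif category == "near_zero_zero":
        lon, lat = _jitter_near((0.0, 0.0), 0.4, rng)
        table.loc[i, ["decimalLongitude", "decimalLatitude"]] = (lon, lat)
    elif category == "near_capital":
        pt = refs.capitals[rng.integers(len(refs.capitals))]
        # 10 km removal radius; place well inside (~5 km ≈ 0.045 deg)
        lon, lat = _jitter_near(pt, 0.04, rng)
        table.loc[i, ["decimalLongitude", "decimalLatitude"]] = (lon, lat)
    elif category == "near_centroid":
        pt = refs.centroids[rng.integers(len(refs.centroids))]
        lon, lat = _jitter_near(pt, 0.004, rng)  # inside the 1 km radius
        table.loc[i, ["decimalLongitude", "decimalLatitude"]] = (lon, lat)
    elif category == "near_institution":
        pt = refs.institutions[rng.integers(len(refs.institutions))]
        lon, lat = _jitter_near(pt, 0.0004, rng)  # inside the 100 m radius
        table.loc[i, ["decimalLongitude", "decimalLatitude"]] = (lon, lat)
    elif category == "near_hq":
        pt = refs.hq[rng.integers(len(refs.hq))]
        lon, lat = _jitter_near(pt, 0.4, rng)  # inside the 0.5 deg radius
        table.loc[i, ["decimalLongitude", "decimalLatitude"]] = (lon, lat)
    else:
        raise ValueError(f"unknown dirty category {category!r}")
    table.loc[i, "provenance"] = category
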