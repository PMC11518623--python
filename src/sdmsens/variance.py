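"""Variance partitioning (sequential ANOVA eta-squared) and the
overlap -> suitability linear mixed model.

The eta-squared partition divides the total sum of squares of the projected
suitable-cell count among island size (a continuous covariate consuming one
df before the factors), island, species and model (predictor set) identity,
their three two-way interactions, and the residual; sums of squares are
sequential (Type I) in that fixed order, so the terms telescope exactly to
the total and the percentages sum to 100.

The mixed model regresses the suitability log-response ratio on the
climatic-overlap log-response ratio with crossed (unnested) random
intercepts for island and species, fitted by REML.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from ._seed import derive_seed

__all__ = [
    "VariancePartition",
    "MixedModelFit",
    "eta_squared_anova",
    "fit_overlap_suitability_lmm",
    "simulate_lrr_design",
]

DEFAULT_TERMS = (
    "island_size",
    "C(island)",
    "C(species)",
    "C(model)",
    "C(island):C(species)",
    "C(island):C(model)",
    "C(species):C(model)",
)


@dataclass
class VariancePartition:
    """Ordered (term, SSQ, df, eta-squared percent) rows plus the residual."""

    terms: list[tuple[str, float, int, float]]
    total_ss: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.terms, columns=["term", "ssq", "df", "eta_sq_percent"]
        )

    def eta(self, term: str) -> float:
        for name, _, _, eta in self.terms:
            if name == term:
                return eta
        raise KeyError(term)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of a least-squares fit and the design rank.

    lstsq handles rank deficiency (aliased columns contribute nothing),
    matching R's pivoting behaviour for sequential ANOVA on designs where,
    for example, island size is a deterministic function of island identity.
    """
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def eta_squared_anova(
    table: pd.DataFrame,
    response: str = "n_suitable",
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> VariancePartition:
    """Sequential (Type I) sum-of-squares partition with eta-squared.

    ``table`` needs the response column plus ``island_size``, ``island``,
    ``species`` and ``model`` (or whatever the ``terms`` formulas name).
    eta-squared(term) = SSQ(term) / total SSQ x 100, with the residual in
    the denominator, so the percentages sum to exactly 100.

    A term that adds no estimable information at all (zero additional rank,
    fully aliased with earlier terms) raises an error naming it; partial
    aliasing is tolerated and absorbs only the estimable part, as in R.
    """
    data = table.dropna(subset=[response]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no usable rows in the ANOVA table")
    y = data[response].to_numpy(float)
    formula = "0 + " + " + ".join(terms)
    design = patsy.dmatrix(formula, data, return_type="dataframe")
    info = design.design_info
    # keep the caller's sequential order (patsy reorders numeric terms)
    term_slices = []
    for name in terms:
        if name not in info.term_name_slices:
            raise KeyError(f"term {name!r} missing from the design")
        term_slices.append((name, info.term_name_slices[name]))

    n = len(y)
    intercept = np.ones((n, 1))
    rss_prev, rank_prev = _rss(y, intercept)
    total_ss = rss_prev  # SS about the mean
    X = intercept
    rows: list[tuple[str, float, int, float]] = []
    for name, sl in term_slices:
        X = np.hstack([X, design.iloc[:, sl].to_numpy(float)])
        rss_new, rank_new = _rss(y, X)
        df_term = rank_new - rank_prev
        block_cols = sl.stop - sl.start
        if df_term == 0 and block_cols > 0 and rss_prev - rss_new < 1e-9 * max(total_ss, 1.0):
            raise ValueError(
                f"rank-deficient design: term {name!r} is fully aliased with "
                "preceding terms"
            )
        ss_term = max(rss_prev - rss_new, 0.0)
        rows.append((name, ss_term, df_term, np.nan))
        rss_prev, rank_prev = rss_new, rank_new
    residual_ss = rss_prev
    rows.append(("residual", residual_ss, n - rank_prev, np.nan))

    if total_ss <= 0:
        # constant response: define the partition as all-residual
        out = [(name, ss, df, 0.0) for name, ss, df, _ in rows[:-1]]
        out.append(("residual", residual_ss, n - rank_prev, 100.0))
        return VariancePartition(terms=out, total_ss=total_ss)

    out = [
        (name, ss, df, 100.0 * ss / total_ss) for name, ss, df, _ in rows
    ]
    return VariancePartition(terms=out, total_ss=total_ss)


@dataclass
class MixedModelFit:
    """Fixed slope and crossed random-intercept summary of the LRR model."""

    slope: float
    slope_se: float
    intercept: float
    island_sd: float
    species_sd: float
    residual_sd: float
    loglik: float
    n: int
    converged: bool
    singular: list[str] = field(default_factory=list)
    method: str = "reml"

    @property
    def slope_ci(self) -> tuple[float, float]:
        """Wald 95% interval for the fixed slope."""
        half = 1.959963984540054 * self.slope_se
        return (self.slope - half, self.slope + half)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "slope",
                "slope_se",
                "intercept",
                "island_sd",
                "species_sd",
                "residual_sd",
                "loglik",
                "n",
                "converged",
                "singular",
                "method",
            )
        }
        d["slope_ci"] = list(self.slope_ci)
        return d


def fit_overlap_suitability_lmm(
    lrr_table: pd.DataFrame,
    response: str = "lrr_suitability",
    predictor: str = "lrr_overlap",
) -> MixedModelFit:
    """REML mixed model: response ~ predictor + (1|island) + (1|species).

    Island and species enter as crossed (unnested) random intercepts,
    implemented as variance components over a single grouping of all rows.
    Requires at least two islands and two species.  A numerically exact
    linear relationship (zero residual variance) degenerates REML, so that
    case is detected and returned via ordinary least squares with zero
    random-effect standard deviations.  Singular (zero-variance) random
    effects are reported in ``singular``, never hidden.
    """
    df = lrr_table.dropna(subset=[response, predictor, "island", "species"]).copy()
    n = len(df)
    if df["island"].nunique() < 2 or df["species"].nunique() < 2:
        raise ValueError("need at least 2 islands and 2 species in the LRR table")
    y = df[response].to_numpy(float)
    x = df[predictor].to_numpy(float)

    # degenerate exact-fit guard: REML is undefined at zero residual scale
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(float(y @ y), 1.0):
        return MixedModelFit(
            slope=float(coef[1]),
            slope_se=0.0,
            intercept=float(coef[0]),
            island_sd=0.0,
            species_sd=0.0,
            residual_sd=0.0,
            loglik=np.inf,
            n=n,
            converged=True,
            singular=["island", "species", "residual"],
            method="ols-degenerate",
        )

    df["_y"] = y
    df["_x"] = x
    model = sm.MixedLM.from_formula(
        "_y ~ _x",
        groups=np.ones(n),
        vc_formula={"island": "0 + C(island)", "species": "0 + C(species)"},
        data=df,
    )
    # variance components on the boundary (a zero island or species
    # variance) defeat some gradient optimizers; walk a fallback sequence
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            candidate = model.fit(reml=True, method=method, maxiter=2000)
            if candidate.converged:
                fit = candidate
                break
    if fit is None:
        raise RuntimeError(
            "mixed model did not converge under any optimizer; "
            f"n={n}, islands={df['island'].nunique()}, "
            f"species={df['species'].nunique()}"
        )
    island_var = float(fit.vcomp[0])
    species_var = float(fit.vcomp[1])
    singular = [
        name
        for name, var in (("island", island_var), ("species", species_var))
        if var < 1e-10
    ]
    return MixedModelFit(
        slope=float(fit.fe_params["_x"]),
        slope_se=float(fit.bse["_x"]),
        intercept=float(fit.fe_params["Intercept"]),
        island_sd=float(np.sqrt(max(island_var, 0.0))),
        species_sd=float(np.sqrt(max(species_var, 0.0))),
        residual_sd=float(np.sqrt(max(fit.scale, 0.0))),
        loglik=float(fit.llf),
        n=n,
        converged=bool(fit.converged),
        singular=singular,
    )


def simulate_lrr_design(
    n_species: int = 142,
    n_islands: int = 8,
    n_comparisons: int = 6,
    slope: float = 1.458,
    intercept: float = 0.0,
    island_sd: float = 0.9,
    species_sd: float = 1.3,
    residual_sd: float = 1.0,
    predictor_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic LRR table from the crossed random-intercept model.

    Mirrors the full study design (142 species x 8 islands x 6 comparisons
    by default) for parameter-recovery checks of the mixed model.
    """
    rng = np.random.default_rng(derive_seed(seed, "lmm_sim"))
    n = n_species * n_islands * n_comparisons
    species = np.repeat(np.arange(n_species), n_islands * n_comparisons)
    island = np.tile(np.repeat(np.arange(n_islands), n_comparisons), n_species)
    x = rng.normal(0.0, predictor_sd, n)
    b_island = rng.normal(0.0, island_sd, n_islands)
    b_species = rng.normal(0.0, species_sd, n_species)
    y = (
        intercept
        + slope * x
        + b_island[island]
        + b_species[species]
        + rng.normal(0.0, residual_sd, n)
    )
    return pd.DataFrame(
        {
            "species": [f"sp{i:03d}" for i in species],
            "island": [f"isl{i}" for i in island],
            "lrr_overlap": x,
            "lrr_suitability": y,
        }
    )
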