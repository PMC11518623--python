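"""End-to-end orchestration of the predictor-set sensitivity experiment.

``run_experiment`` executes the full chain — simulate climate domains,
sample and prepare occurrences, fit the SDM battery per predictor set,
project binaries onto the islands, compute niche overlaps and LRR pairs,
partition variance and fit the mixed model — from a single
:class:`ExperimentConfig`, with one pipeline seed deterministically deriving
every stage seed.  ``make_nonanalogue_scenario`` ships the designed
non-analogue study: a calibration domain where a summer-like and a
winter-like temperature variable are correlated at r = 0.9, and projection
islands where the pair is decoupled and the summer-like variable is shifted
below every species' occupied range while the winter-like variable stays
inside it.
"""
from __future__ import annotations

import json
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seed import derive_seed
from .grids import ClimateStack
from .occurrences import (
    PrepConfig,
    clean_records,
    draw_pseudo_absences,
    quadrant_regions,
    snap_to_grid,
    thin_records,
)
from .overlap import (
    ClimaticRange,
    island_climate_range,
    pair_lrrs,
    select_baseline,
    variable_overlap,
    weighted_cumulative_overlap,
)
from .projection import (
    confusion_by_island,
    island_presence,
    project_binary,
    suitability_matrix,
)
from .sdm import (
    EnsembleModel,
    PredictorSet,
    SDMConfig,
    build_ensemble,
    check_collinearity,
    fit_battery,
    member_tss_table,
)
from .synthetic import (
    BiasLayer,
    DomainConfig,
    GaussianResponse,
    LogisticResponse,
    NicheSpec,
    generate_climate_domain,
    gradient_bias,
    make_projection_domain,
    sample_occurrences,
    uniform_bias,
)
from .variance import eta_squared_anova, fit_overlap_suitability_lmm

__all__ = [
    "IslandSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "make_nonanalogue_scenario",
    "predictor_contrast",
]


@dataclass
class IslandSpec:
    """One projection island derived from the calibration domain config.

    ``sd_scale`` shrinks (or stretches) the per-variable standard deviation
    relative to the calibration domain: a small island spans a much narrower
    climatic band than a global calibration extent.
    """

    name: str
    n_rows: int
    n_cols: int
    decouple: tuple[tuple[str, str], ...] = ()
    range_shift: dict[str, float] = field(default_factory=dict)
    sd_scale: float = 1.0
    group: str | None = None


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, under a single pipeline seed."""

    seed: int
    calibration: DomainConfig
    islands: list[IslandSpec]
    species: list[NicheSpec]
    predictor_sets: list[PredictorSet]
    prep: PrepConfig = field(default_factory=PrepConfig)
    sdm: SDMConfig = field(default_factory=SDMConfig)
    n_occurrences: int = 300
    dirty_fraction: float = 0.0
    bias_kind: str = "uniform"  # "uniform" | "gradient"
    recorded: dict[str, list[str]] | None = None
    island_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        available = set(self.calibration.variables)
        for sp in self.species:
            missing = set(sp.responses) - available
            if missing:
                raise ValueError(
                    f"species {sp.species_id!r} references unknown variables "
                    f"{sorted(missing)}"
                )
        for ps in self.predictor_sets:
            missing = set(ps.variables) - available
            if missing:
                raise ValueError(
                    f"predictor set {ps.id!r} references unknown variables "
                    f"{sorted(missing)}"
                )
        if self.bias_kind not in ("uniform", "gradient"):
            raise ValueError("bias_kind must be 'uniform' or 'gradient'")

    # -- config file round trip ----------------------------------------
    def to_dict(self) -> dict:
        def niche(sp: NicheSpec) -> dict:
            resp = {}
            for var, r in sp.responses.items():
                if isinstance(r, GaussianResponse):
                    resp[var] = {"kind": "gaussian", **asdict(r)}
                else:
                    resp[var] = {"kind": "logistic", **asdict(r)}
            return {
                "species_id": sp.species_id,
                "responses": resp,
                "combination": sp.combination,
                "prevalence_target": sp.prevalence_target,
            }

        cal = asdict(self.calibration)
        cal["correlation"] = self.calibration.correlation.tolist()
        cal["mean"] = self.calibration.mean.tolist()
        cal["sd"] = self.calibration.sd.tolist()
        cal["variables"] = list(self.calibration.variables)
        return {
            "seed": self.seed,
            "calibration": cal,
            "islands": [asdict(i) for i in self.islands],
            "species": [niche(sp) for sp in self.species],
            "predictor_sets": [
                {"id": p.id, "variables": list(p.variables)}
                for p in self.predictor_sets
            ],
            "prep": {**asdict(self.prep), "reference_points": None},
            "sdm": asdict(self.sdm),
            "n_occurrences": self.n_occurrences,
            "dirty_fraction": self.dirty_fraction,
            "bias_kind": self.bias_kind,
            "recorded": self.recorded,
            "island_groups": self.island_groups,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        def niche(nd: Mapping) -> NicheSpec:
            responses = {}
            for var, r in nd["responses"].items():
                r = dict(r)
                kind = r.pop("kind")
                responses[var] = (
                    GaussianResponse(**r) if kind == "gaussian" else LogisticResponse(**r)
                )
            return NicheSpec(
                species_id=nd["species_id"],
                responses=responses,
                combination=nd.get("combination", "product"),
                prevalence_target=nd.get("prevalence_target", 1.0),
            )

        cal = dict(d["calibration"])
        cal["variables"] = tuple(cal["variables"])
        prep_kwargs = {
            k: v for k, v in dict(d.get("prep", {})).items() if v is not None
        }
        prep_kwargs.pop("reference_points", None)
        islands = []
        for idd in d["islands"]:
            idd = dict(idd)
            idd["decouple"] = tuple(tuple(p) for p in idd.get("decouple", ()))
            islands.append(IslandSpec(**idd))
        return cls(
            seed=d["seed"],
            calibration=DomainConfig(**cal),
            islands=islands,
            species=[niche(nd) for nd in d["species"]],
            predictor_sets=[
                PredictorSet(id=p["id"], variables=tuple(p["variables"]))
                for p in d["predictor_sets"]
            ],
            prep=PrepConfig(**prep_kwargs),
            sdm=SDMConfig(**{
                k: tuple(v) if k == "algorithms" else v
                for k, v in dict(d.get("sdm", {})).items()
            }),
            n_occurrences=d.get("n_occurrences", 300),
            dirty_fraction=d.get("dirty_fraction", 0.0),
            bias_kind=d.get("bias_kind", "uniform"),
            recorded=d.get("recorded"),
            island_groups=d.get("island_groups"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ExperimentResult:
    """All stage outputs of one experiment run."""

    config: ExperimentConfig
    calibration: ClimateStack
    islands: dict[str, ClimateStack]
    bias: BiasLayer
    prepared: dict[str, dict]  # species -> {presences, pa_tables, audit}
    ensembles: dict[tuple[str, str], EnsembleModel]  # (species, set) -> model
    member_tss: pd.DataFrame
    set_mean_tss: pd.DataFrame
    suitability: pd.DataFrame
    island_confusion: pd.DataFrame | None
    per_variable_overlap: pd.DataFrame
    omega: pd.DataFrame
    baseline: str
    lrr_table: pd.DataFrame
    anova: "pd.DataFrame"
    lmm: dict | None
    manifest: dict

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.member_tss.to_csv(out / "member_tss.csv", index=False)
        self.set_mean_tss.to_csv(out / "set_mean_tss.csv", index=False)
        self.suitability.to_csv(out / "suitability_matrix.csv", index=False)
        self.per_variable_overlap.to_csv(
            out / "per_variable_overlap.csv", index=False
        )
        self.omega.to_csv(out / "cumulative_overlap.csv", index=False)
        self.lrr_table.to_csv(out / "lrr_table.csv", index=False)
        self.anova.to_csv(out / "anova_eta_squared.csv", index=False)
        if self.island_confusion is not None:
            self.island_confusion.to_csv(out / "island_confusion.csv", index=False)
        if self.lmm is not None:
            (out / "lmm_fit.json").write_text(json.dumps(self.lmm, indent=2))
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def _stage_simulate(cfg: ExperimentConfig):
    from dataclasses import replace

    cal_cfg = cfg.calibration
    if cal_cfg.seed != cfg.seed:
        cal_cfg = replace(cal_cfg, seed=derive_seed(cfg.seed, "calibration"))
    calibration = generate_climate_domain(cal_cfg)
    islands = {}
    for spec in cfg.islands:
        base = cal_cfg
        if spec.sd_scale != 1.0:
            base = replace(cal_cfg, sd=cal_cfg.sd * spec.sd_scale)
        islands[spec.name] = make_projection_domain(
            base,
            decouple=spec.decouple,
            range_shift=spec.range_shift,
            name=spec.name,
            n_rows=spec.n_rows,
            n_cols=spec.n_cols,
            seed=derive_seed(cfg.seed, "island", spec.name),
        )
    bias = (
        gradient_bias(calibration)
        if cfg.bias_kind == "gradient"
        else uniform_bias(calibration)
    )
    return calibration, islands, bias


def _stage_prepare(cfg: ExperimentConfig, calibration, bias):
    regions = quadrant_regions(calibration)
    metric = "haversine" if calibration.geometry.geographic else "euclidean"
    prep = cfg.prep
    if prep.metric != metric:
        from dataclasses import replace

        prep = replace(prep, metric=metric)
    prepared: dict[str, dict] = {}
    for sp in cfg.species:
        seed = derive_seed(cfg.seed, "prepare", sp.species_id)
        raw = sample_occurrences(
            sp,
            calibration,
            bias,
            n_target=cfg.n_occurrences,
            dirty_fraction=cfg.dirty_fraction,
            seed=seed,
            year_cutoff=prep.year_cutoff,
            max_uncertainty=prep.max_uncertainty,
            reference_points=prep.reference_points,
        )
        cleaned, clean_audit = clean_records(raw, prep)
        snapped, snap_audit = snap_to_grid(cleaned, calibration)
        thinned = thin_records(
            snapped,
            prep.thin_distance,
            reps=prep.thin_reps,
            seed=derive_seed(seed, "thin"),
            metric=metric,
        )
        entry: dict = {
            "audit": {
                "n_raw": len(raw),
                "clean": clean_audit,
                "snap": snap_audit,
                "n_cleaned": len(cleaned),
                "n_snapped": len(snapped),
                "n_thinned": len(thinned),
            }
        }
        try:
            pa_sets = draw_pseudo_absences(
                thinned, calibration, bias, regions, prep, seed=derive_seed(seed, "pa")
            )
        except ValueError as exc:
            entry["status"] = f"failed: {exc}"
            prepared[sp.species_id] = entry
            continue
        variables = list(calibration.variables)
        presences = thinned.copy()
        pres_vals = calibration.values_at(
            presences["decimalLongitude"], presences["decimalLatitude"], variables
        )
        for v in variables:
            presences[v] = pres_vals[v].to_numpy()
        pa_tables = []
        for pa in pa_sets:
            t = pa.cells.copy()
            vals = calibration.values_at(
                t["decimalLongitude"], t["decimalLatitude"], variables
            )
            for v in variables:
                t[v] = vals[v].to_numpy()
            pa_tables.append(t)
        entry.update(
            {"status": "ok", "presences": presences, "pa_tables": pa_tables}
        )
        prepared[sp.species_id] = entry
    return prepared


def _stage_fit(cfg: ExperimentConfig, calibration, prepared):
    for pset in cfg.predictor_sets:
        check_collinearity(pset, calibration)
    ensembles: dict[tuple[str, str], EnsembleModel] = {}
    all_members = []
    for sp_id, entry in prepared.items():
        if entry.get("status") != "ok":
            continue
        presences = entry["presences"]
        pa_tables = entry["pa_tables"]
        pooled = pd.concat([presences] + pa_tables, ignore_index=True)
        labels = np.concatenate(
            [np.ones(len(presences))]
            + [np.zeros(len(t)) for t in pa_tables]
        ).astype(int)
        for pset in cfg.predictor_sets:
            seed = derive_seed(cfg.seed, "fit", sp_id, pset.id)
            members = fit_battery(presences, pa_tables, pset, cfg.sdm, seed=seed)
            mt = member_tss_table(members)
            mt.insert(0, "species", sp_id)
            all_members.append(mt)
            ens = build_ensemble(
                members,
                pooled,
                labels,
                tss_min=cfg.sdm.tss_min,
                n_perm=cfg.sdm.n_perm,
                seed=derive_seed(seed, "vi"),
            )
            ensembles[(sp_id, pset.id)] = ens
    member_tss = (
        pd.concat(all_members, ignore_index=True)
        if all_members
        else pd.DataFrame()
    )
    if len(member_tss):
        set_mean = (
            member_tss[member_tss["status"] == "ok"]
            .groupby("predictor_set", as_index=False)["tss"]
            .mean()
            .rename(columns={"tss": "mean_member_tss"})
        )
    else:
        set_mean = pd.DataFrame(columns=["predictor_set", "mean_member_tss"])
    return ensembles, member_tss, set_mean


def _stage_project(cfg: ExperimentConfig, islands, ensembles):
    grids = []
    failed = []
    for (sp_id, pset_id), ens in ensembles.items():
        for isl_name, isl_stack in islands.items():
            if ens.failed:
                failed.append((sp_id, isl_name, pset_id))
            else:
                grids.append(project_binary(ens, isl_stack, species=sp_id))
    matrix = suitability_matrix(grids, failed, groups=cfg.island_groups)
    confusion = None
    if cfg.recorded:
        pool = sorted(
            {sp for (sp, ps), e in ensembles.items() if not e.failed}
        )
        pset_ids = sorted({ps for (_, ps) in ensembles})
        rows = []
        for isl_name in islands:
            recorded = cfg.recorded.get(isl_name, [])
            for pset_id in pset_ids:
                predictions = {}
                for g in grids:
                    if g.island == isl_name and g.predictor_set == pset_id:
                        predictions[g.species] = island_presence(g)
                ev = confusion_by_island(predictions, recorded, pool)
                rows.append(
                    {
                        "island": isl_name,
                        "predictor_set": pset_id,
                        "sensitivity": ev.sensitivity if ev else np.nan,
                        "specificity": ev.specificity if ev else np.nan,
                        "tss": ev.tss if ev else np.nan,
                    }
                )
        confusion = pd.DataFrame(rows)
    return grids, matrix, confusion


def _stage_overlap(cfg: ExperimentConfig, calibration, islands, prepared, ensembles):
    groups: dict[str, list[str]] = {}
    for name in islands:
        g = (cfg.island_groups or {}).get(name, name)
        groups.setdefault(g, []).append(name)
    ranges = {
        g: ClimaticRange.combine(
            [island_climate_range(islands[n]) for n in names], island=g
        )
        for g, names in groups.items()
    }
    variables = list(calibration.variables)
    pv_rows = []
    for sp_id, entry in prepared.items():
        if entry.get("status") != "ok":
            continue
        presences = entry["presences"]
        for g, rng_ in ranges.items():
            for v in variables:
                pv_rows.append(
                    {
                        "species": sp_id,
                        "island": g,
                        "variable": v,
                        "overlap": variable_overlap(
                            presences[v].to_numpy(), rng_.bounds[v]
                        ),
                    }
                )
    per_variable = pd.DataFrame(pv_rows)
    ov_lookup = {
        (r["species"], r["island"], r["variable"]): r["overlap"] for r in pv_rows
    }

    om_rows = []
    for (sp_id, pset_id), ens in ensembles.items():
        if ens.failed:
            continue
        for g in ranges:
            ov = {
                v: ov_lookup[(sp_id, g, v)]
                for v in ens.predictor_set.variables
            }
            vi = {
                v: ens.variable_importances.get(v, 0.0)
                for v in ens.predictor_set.variables
            }
            om_rows.append(
                {
                    "species": sp_id,
                    "island": g,
                    "predictor_set": pset_id,
                    "omega": weighted_cumulative_overlap(ov, vi),
                }
            )
    omega = pd.DataFrame(om_rows)
    return per_variable, omega


def _stage_partition(matrix: pd.DataFrame, lrr_table: pd.DataFrame):
    anova_df = matrix.rename(columns={"predictor_set": "model"}).copy()
    anova_df["island_size"] = anova_df["n_land_cells"]
    anova_error = None
    try:
        anova = eta_squared_anova(anova_df, response="n_suitable").as_frame()
    except ValueError as exc:
        # a degenerate design (e.g. every ensemble of one species x model
        # cell failed) should not kill the rest of the experiment
        anova = pd.DataFrame(columns=["term", "ssq", "df", "eta_sq_percent"])
        anova_error = str(exc)
    lmm = None
    if len(lrr_table) and lrr_table["island"].nunique() >= 2:
        try:
            lmm = fit_overlap_suitability_lmm(lrr_table).to_dict()
        except RuntimeError as exc:  # non-convergence on tiny designs
            lmm = {"error": str(exc)}
    return anova, lmm, anova_error


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    resume: bool = False,
) -> ExperimentResult:
    """Execute every stage in order and return the collected outputs.

    With ``out_dir`` set, summary tables and a manifest are written there,
    stage intermediates are pickled under ``out_dir/stages``, and with
    ``resume=True`` any stage whose pickle already exists is loaded instead
    of recomputed (delete a stage file to regenerate exactly that stage).
    """
    stage_dir = None
    if out_dir is not None:
        stage_dir = Path(out_dir) / "stages"
        stage_dir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    def cached(name: str, fn):
        if stage_dir is not None and resume:
            f = stage_dir / f"{name}.pkl"
            if f.exists():
                with open(f, "rb") as fh:
                    return pickle.load(fh)
        t0 = time.perf_counter()
        value = fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        if stage_dir is not None:
            with open(stage_dir / f"{name}.pkl", "wb") as fh:
                pickle.dump(value, fh)
        return value

    calibration, islands, bias = cached(
        "simulate", lambda: _stage_simulate(config)
    )
    prepared = cached(
        "prepare", lambda: _stage_prepare(config, calibration, bias)
    )
    ensembles, member_tss, set_mean_tss = cached(
        "fit", lambda: _stage_fit(config, calibration, prepared)
    )
    grids, matrix, confusion = cached(
        "project", lambda: _stage_project(config, islands, ensembles)
    )
    per_variable, omega = cached(
        "overlap",
        lambda: _stage_overlap(config, calibration, islands, prepared, ensembles),
    )
    baseline = select_baseline(omega) if len(omega) else ""
    lrr_table = (
        pair_lrrs(matrix, omega, baseline) if baseline else pd.DataFrame()
    )
    anova, lmm, anova_error = cached(
        "partition", lambda: _stage_partition(matrix, lrr_table)
    )

    n_failed = sum(1 for e in ensembles.values() if e.failed)
    manifest = {
        "anova_error": anova_error,
        "seed": config.seed,
        "n_species": len(config.species),
        "n_islands": len(config.islands),
        "predictor_sets": [p.id for p in config.predictor_sets],
        "baseline": baseline,
        "n_failed_ensembles": n_failed,
        "n_modelled": len(ensembles) - n_failed,
        "species_audits": {
            sp: entry["audit"] for sp, entry in prepared.items()
        },
        "timings_s": timings,
        "lrr_rows": int(len(lrr_table)),
    }
    result = ExperimentResult(
        config=config,
        calibration=calibration,
        islands=islands,
        bias=bias,
        prepared=prepared,
        ensembles=ensembles,
        member_tss=member_tss,
        set_mean_tss=set_mean_tss,
        suitability=matrix,
        island_confusion=confusion,
        per_variable_overlap=per_variable,
        omega=omega,
        baseline=baseline,
        lrr_table=lrr_table,
        anova=anova,
        lmm=lmm,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write_outputs(out_dir)
    return result


def predictor_contrast(
    matrix: pd.DataFrame, set_low: str, set_high: str
) -> pd.DataFrame:
    """Per-species mean projected fraction under two predictor sets.

    Returns columns species, fraction_low, fraction_high and diff
    (high - low), averaging fraction_suitable over islands.
    """
    mean_frac = (
        matrix.dropna(subset=["fraction_suitable"])
        .groupby(["species", "predictor_set"])["fraction_suitable"]
        .mean()
        .unstack("predictor_set")
    )
    out = pd.DataFrame(
        {
            "species": mean_frac.index,
            "fraction_low": mean_frac[set_low].to_numpy(),
            "fraction_high": mean_frac[set_high].to_numpy(),
        }
    ).reset_index(drop=True)
    out["diff"] = out["fraction_high"] - out["fraction_low"]
    return out


# ---------------------------------------------------------------------------
# the shipped non-analogue scenario
# ---------------------------------------------------------------------------
SCENARIO_SETS = {
    "summer": "BIO5_12_15",
    "annual": "BIO1_12_15",
    "winter": "BIO6_12_15",
}


def make_nonanalogue_scenario(
    seed: int = 0, n_species: int = 20
) -> ExperimentConfig:
    """The designed non-analogue study preset.

    Calibration domain: summer-like (BIO5) and winter-like (BIO6)
    temperature variables correlated at r = 0.9, an annual-mean-like
    blend of the two (BIO1, correlated 0.97 with each), plus two
    precipitation variables (annual amount BIO12, seasonality BIO15).
    Virtual species are limited by BIO5 (Gaussian responses, optima
    spread around the domain mean) with a broad secondary response to
    BIO12.  Projection islands decouple the temperature trio and shift
    BIO5 six to eight standard deviations below the calibration mean —
    below every species' occupied range — and BIO1, as the summer/winter
    blend, by half of that; BIO6 and both precipitation variables stay
    inside their calibration ranges.  Three predictor sets differ only in
    temperature identity (summer / annual / winter), giving a gradation
    from strongly under- to strongly over-projecting models.
    """
    variables = ("BIO1", "BIO5", "BIO6", "BIO12", "BIO15")
    corr = np.array(
        [
            [1.0, 0.97, 0.97, 0.0, 0.0],
            [0.97, 1.0, 0.9, 0.0, 0.0],
            [0.97, 0.9, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0, 0.3],
            [0.0, 0.0, 0.0, 0.3, 1.0],
        ]
    )
    mean = np.array([8.5, 15.0, 2.0, 1200.0, 40.0])
    sd = np.array([3.0, 3.0, 3.0, 300.0, 10.0])
    calibration = DomainConfig(
        name="calibration",
        n_rows=80,
        n_cols=80,
        variables=variables,
        correlation=corr,
        mean=mean,
        sd=sd,
        cell_size=1.0,
        spatial_smoothness=2.5,
        seed=derive_seed(seed, "calibration"),
    )

    # niche breadths well below the background climatic spread: species must
    # be genuinely climate-limited for the battery to discriminate presences
    # from background (internal member TSS then sits around 0.6-0.8)
    rng = np.random.default_rng(derive_seed(seed, "species_roster"))
    i5, i12 = variables.index("BIO5"), variables.index("BIO12")
    species = []
    for i in range(n_species):
        opt5 = float(mean[i5] + rng.uniform(-1.0, 1.0) * sd[i5])
        br5 = float(rng.uniform(0.2, 0.4) * sd[i5])
        opt12 = float(mean[i12] + rng.uniform(-0.5, 0.5) * sd[i12])
        br12 = float(rng.uniform(0.5, 0.9) * sd[i12])
        species.append(
            NicheSpec(
                species_id=f"sp{i:02d}",
                responses={
                    "BIO5": GaussianResponse(optimum=opt5, breadth=br5),
                    "BIO12": GaussianResponse(optimum=opt12, breadth=br12),
                },
                combination="product",
            )
        )

    # islands: small areas, hence a narrow internal climatic band
    # (sd_scale 0.5); the summer-like variable is shifted far below the
    # occupied range, the annual blend by half of that, the winter-like
    # and precipitation variables stay inside their calibration ranges
    shift5 = {"islandA": -6.0, "islandB": -7.0, "islandC": -8.0}
    islands = [
        IslandSpec(
            name=name,
            n_rows=size,
            n_cols=size,
            decouple=(("BIO5", "BIO6"), ("BIO1", "BIO5"), ("BIO1", "BIO6")),
            # the annual blend shifts far less than summer (mild winters
            # compensate): 0.3x keeps island BIO1 within reach of the
            # cold-adapted species' optima, giving the intermediate
            # projections the summer/annual/winter gradation needs
            range_shift={
                "BIO5": s * float(sd[i5]),
                "BIO1": 0.3 * s * float(sd[i5]),
            },
            sd_scale=0.5,
        )
        for (name, s), size in zip(shift5.items(), (20, 25, 30))
    ]

    predictor_sets = [
        PredictorSet(id=SCENARIO_SETS["summer"], variables=("BIO5", "BIO12", "BIO15")),
        PredictorSet(id=SCENARIO_SETS["annual"], variables=("BIO1", "BIO12", "BIO15")),
        PredictorSet(id=SCENARIO_SETS["winter"], variables=("BIO6", "BIO12", "BIO15")),
    ]

    # the recorded island checklist is an external input in a real study; a
    # seeded random subset of the roster stands in for it (synthetic)
    rec_rng = np.random.default_rng(derive_seed(seed, "recorded"))
    recorded = {
        isl.name: [
            sp.species_id for sp in species if rec_rng.uniform() < 0.4
        ]
        for isl in islands
    }

    prep = PrepConfig(
        metric="euclidean",
        thin_distance=2.0,
        thin_reps=10,
        pa_draws=2,
    )
    sdm = SDMConfig(
        algorithms=("glm", "rf"),
        n_splits=2,
        rf_trees=100,
        n_perm=10,
    )
    return ExperimentConfig(
        seed=seed,
        calibration=calibration,
        islands=islands,
        species=species,
        predictor_sets=predictor_sets,
        prep=prep,
        sdm=sdm,
        n_occurrences=300,
        dirty_fraction=0.1,
        bias_kind="gradient",
        recorded=recorded,
    )
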