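"""Multi-algorithm SDM battery, TSS evaluation, ensembles, importance.

Four algorithm families relate presences to pseudo-absences: an unpenalised
logistic regression with quadratic terms (GLM), a spline-logistic model
(GAM analogue), bagged trees (random forest) and boosted trees (BRT).
Each member model is fitted per pseudo-absence draw and per random 70/30
split, evaluated by the true skill statistic (TSS = sensitivity +
specificity - 1) at its own maxTSS threshold on the held-out 30%, and
members with TSS > 0.5 form an unweighted-mean committee.  The committee's
binarisation threshold is the maxTSS cutoff of the ensemble scores; variable
importance is the permutation convention 1 - Pearson r between intact and
single-variable-permuted predictions, averaged over permutations and
committee members.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, SplineTransformer, StandardScaler

from ._seed import derive_seed
from .grids import ClimateStack

__all__ = [
    "PredictorSet",
    "STANDARD_PREDICTOR_SETS",
    "Evaluation",
    "SDMConfig",
    "FittedModel",
    "EnsembleModel",
    "split_data",
    "evaluate_tss",
    "max_tss_threshold",
    "fit_battery",
    "build_ensemble",
    "variable_importance",
    "check_collinearity",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("glm", "gam", "rf", "brt")


@dataclass(frozen=True)
class PredictorSet:
    """A named list of predictor variables for one model."""

    id: str
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(set(self.variables)) != len(self.variables):
            raise ValueError(f"predictor set {self.id!r} has duplicate variables")
        if not self.variables:
            raise ValueError("predictor set must contain at least one variable")


def _pset(*bios: int) -> PredictorSet:
    return PredictorSet(
        id="BIO" + "_".join(str(b) for b in bios),
        variables=tuple(f"BIO{b}" for b in bios),
    )


#: The seven four-variable sets of the sensitivity design: two temperature
#: descriptors varied, annual precipitation (BIO12) and precipitation
#: seasonality (BIO15) held constant.
STANDARD_PREDICTOR_SETS: dict[str, PredictorSet] = {
    p.id: p
    for p in (
        _pset(1, 3, 12, 15),
        _pset(1, 7, 12, 15),
        _pset(2, 5, 12, 15),
        _pset(2, 6, 12, 15),
        _pset(3, 5, 12, 15),
        _pset(5, 7, 12, 15),
        _pset(6, 7, 12, 15),
    )
}


def check_collinearity(
    pset: PredictorSet, calibration: ClimateStack, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """Warn (not error) when a pair in the set has |r| >= threshold.

    Returns the offending pairs with their correlation on the calibration
    land cells.  A warning rather than an error: highly correlated pairs can
    be a deliberate part of a sensitivity design.
    """
    table = calibration.land_table(pset.variables)
    offenders = []
    for i, a in enumerate(pset.variables):
        for b in pset.variables[i + 1 :]:
            r = float(np.corrcoef(table[a], table[b])[0, 1])
            if abs(r) >= threshold:
                offenders.append((a, b, r))
    if offenders:
        msg = ", ".join(f"{a}~{b} r={r:.3f}" for a, b, r in offenders)
        warnings.warn(
            f"predictor set {pset.id!r}: strongly correlated pair(s) {msg}",
            UserWarning,
            stacklevel=2,
        )
    return offenders


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Evaluation:
    """Sensitivity, specificity and their TSS identity."""

    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp, fn, tn, fp


def evaluate_tss(scores, labels, threshold: float) -> Evaluation:
    """Confusion statistics at ``scores >= threshold``.

    Raises if either class is absent (sensitivity or specificity would be
    undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("labels contain a single class; TSS undefined")
    tp, fn, tn, fp = _confusion(scores, labels, threshold)
    return Evaluation(sensitivity=tp / (tp + fn), specificity=tn / (tn + fp))


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus sentinels."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))


def max_tss_threshold(scores, labels) -> float:
    """The cutoff maximising TSS; ties broken toward the lowest threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("labels contain a single class; TSS undefined")
    candidates = _threshold_candidates(scores)
    best_thr = candidates[0]
    best_tss = -np.inf
    for thr in candidates:  # ascending; strict improvement keeps the lowest
        tss = evaluate_tss(scores, labels, thr).tss
        if tss > best_tss + 1e-12:
            best_tss = tss
            best_thr = thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------
def split_data(
    labels, train_fraction: float = 0.7, rep: int = 0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/eval split; returns (train_idx, eval_idx).

    Per-class training counts are ``round(train_fraction * n_class)``;
    partitions are disjoint and exhaustive.  The rep index is folded into
    the derived seed so replicates differ while staying reproducible.
    """
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(derive_seed(seed, "split", rep))
    train_parts, eval_parts = [], []
    for cls in (0, 1):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 5:
            raise ValueError(
                f"class {cls} has only {len(idx)} records; at least 5 required"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_parts.append(idx[:n_train])
        eval_parts.append(idx[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(eval_parts))


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------
@dataclass
class SDMConfig:
    """Battery layout and learner hyper-parameters.

    Defaults mirror a conventional ensemble-SDM setup: four algorithms,
    three random 70/30 splits, five pseudo-absence draws, 500 bagged trees,
    2500 boosted trees at learning rate 0.01 and interaction depth 7,
    quadratic logistic terms and ~4 effective df splines.  All knobs are
    exposed so a smaller synthetic study can scale the battery down.
    """

    algorithms: tuple[str, ...] = ("glm", "gam", "rf", "brt")
    n_splits: int = 3
    train_fraction: float = 0.7
    tss_min: float = 0.5
    rf_trees: int = 500
    rf_min_samples_leaf: int = 5
    brt_trees: int = 2500
    brt_learning_rate: float = 0.01
    brt_depth: int = 7
    gam_knots: int = 5
    n_perm: int = 10  # permutations per variable for importance

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be at least 1")


def _add_squares(X):
    X = np.asarray(X, dtype=float)
    return np.hstack([X, X**2])


def make_estimator(algorithm: str, cfg: SDMConfig, seed: int):
    """Fresh scikit-learn estimator for one battery member."""
    if algorithm == "glm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("quad", FunctionTransformer(_add_squares)),
                ("logit", LogisticRegression(penalty=None, max_iter=2000)),
            ]
        )
    if algorithm == "gam":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "spline",
                    SplineTransformer(
                        n_knots=cfg.gam_knots, degree=3, include_bias=False
                    ),
                ),
                ("logit", LogisticRegression(penalty=None, max_iter=2000)),
            ]
        )
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            min_samples_leaf=cfg.rf_min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "brt":
        return GradientBoostingClassifier(
            n_estimators=cfg.brt_trees,
            learning_rate=cfg.brt_learning_rate,
            max_depth=cfg.brt_depth,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class FittedModel:
    """One battery member with its held-out evaluation."""

    algorithm: str
    predictor_set: PredictorSet
    pa_draw: int
    split: int
    estimator: object
    threshold: float
    tss_eval: float
    evaluation: Evaluation
    seed: int
    status: str = "ok"

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Occurrence probability on rows of predictor columns."""
        X = data[list(self.predictor_set.variables)].to_numpy(float)
        return self.estimator.predict_proba(X)[:, 1]


def fit_battery(
    presences: pd.DataFrame,
    pa_tables: Sequence[pd.DataFrame],
    predictor_set: PredictorSet,
    cfg: SDMConfig | None = None,
    seed: int = 0,
) -> list[FittedModel]:
    """Fit algorithms x splits x pseudo-absence draws member models.

    ``presences`` and each pseudo-absence table must carry the predictor
    columns.  Each member is evaluated on its held-out 30% at its own
    maxTSS threshold.  A member whose learner fails to converge is recorded
    with status ``"failed"`` and excluded downstream.
    """
    cfg = cfg or SDMConfig()
    variables = list(predictor_set.variables)
    for name, tab in [("presence", presences)] + [
        (f"pa_draw {i}", t) for i, t in enumerate(pa_tables)
    ]:
        missing = [v for v in variables if v not in tab.columns]
        if missing:
            raise KeyError(f"{name} table is missing predictor columns {missing}")

    members: list[FittedModel] = []
    X_pres = presences[variables].to_numpy(float)
    for draw_idx, pa in enumerate(pa_tables):
        X_pa = pa[variables].to_numpy(float)
        X = np.vstack([X_pres, X_pa])
        y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_pa))]).astype(int)
        for split_idx in range(cfg.n_splits):
            split_seed = derive_seed(seed, predictor_set.id, "draw", draw_idx)
            train_idx, eval_idx = split_data(
                y, cfg.train_fraction, rep=split_idx, seed=split_seed
            )
            for algorithm in cfg.algorithms:
                member_seed = derive_seed(
                    seed, predictor_set.id, draw_idx, split_idx, algorithm
                )
                est = make_estimator(algorithm, cfg, member_seed)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est.fit(X[train_idx], y[train_idx])
                    scores = est.predict_proba(X[eval_idx])[:, 1]
                    thr = max_tss_threshold(scores, y[eval_idx])
                    ev = evaluate_tss(scores, y[eval_idx], thr)
                    members.append(
                        FittedModel(
                            algorithm=algorithm,
                            predictor_set=predictor_set,
                            pa_draw=draw_idx,
                            split=split_idx,
                            estimator=est,
                            threshold=thr,
                            tss_eval=ev.tss,
                            evaluation=ev,
                            seed=member_seed,
                        )
                    )
                except Exception as exc:  # non-convergence -> failed member
                    logger.warning(
                        "member %s/%s draw %d split %d failed: %s",
                        predictor_set.id,
                        algorithm,
                        draw_idx,
                        split_idx,
                        exc,
                    )
                    members.append(
                        FittedModel(
                            algorithm=algorithm,
                            predictor_set=predictor_set,
                            pa_draw=draw_idx,
                            split=split_idx,
                            estimator=None,
                            threshold=np.nan,
                            tss_eval=np.nan,
                            evaluation=Evaluation(np.nan, np.nan),
                            seed=member_seed,
                            status=f"failed: {exc}",
                        )
                    )
    return members


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------
@dataclass
class EnsembleModel:
    """Committee of members with TSS > tss_min; unweighted-mean combination."""

    predictor_set: PredictorSet
    members: list[FittedModel]
    binarisation_threshold: float = np.nan
    variable_importances: dict[str, float] = field(default_factory=dict)
    status: str = "ok"
    combination: str = "mean"

    @property
    def failed(self) -> bool:
        return self.status != "ok"

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if self.failed:
            raise RuntimeError(
                f"ensemble for {self.predictor_set.id!r} failed: {self.status}"
            )
        scores = np.stack([m.predict(data) for m in self.members])
        return scores.mean(axis=0)


def build_ensemble(
    members: Sequence[FittedModel],
    eval_data: pd.DataFrame,
    eval_labels,
    tss_min: float = 0.5,
    *,
    n_perm: int = 10,
    seed: int = 0,
    compute_importance: bool = True,
) -> EnsembleModel:
    """Assemble the TSS > tss_min committee and its binarisation threshold.

    ``eval_data``/``eval_labels`` are the pooled evaluation records (the
    full presence + pseudo-absence table) on which the ensemble scores are
    thresholded by maxTSS and on which variable importance is permuted.
    An empty committee is a *status*, not an exception — mirroring how
    ensemble construction fails for some species in practice.
    """
    members = list(members)
    if not members:
        raise ValueError("no members supplied")
    pset = members[0].predictor_set
    committee = [
        m for m in members if m.status == "ok" and np.isfinite(m.tss_eval)
        and m.tss_eval > tss_min
    ]
    if not committee:
        return EnsembleModel(
            predictor_set=pset,
            members=[],
            status=f"failed: no member with TSS > {tss_min}",
        )
    ens = EnsembleModel(predictor_set=pset, members=committee)
    scores = ens.predict(eval_data)
    ens.binarisation_threshold = max_tss_threshold(scores, eval_labels)
    if compute_importance:
        ens.variable_importances = variable_importance(
            ens, eval_data, n_perm=n_perm, seed=seed
        )
    return ens


def variable_importance(
    ensemble: EnsembleModel,
    reference: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> dict[str, float]:
    """Permutation importance: 1 - Pearson r(intact, permuted predictions).

    Averaged over ``n_perm`` permutations and over committee members;
    negatives clipped to zero.  A member with zero-variance predictions has
    importance 0 for every variable (it depends on nothing).  Variables not
    in the predictor set score 0.
    """
    if ensemble.failed:
        raise RuntimeError("cannot compute importances of a failed ensemble")
    variables = (
        list(ensemble.predictor_set.variables) if variables is None else list(variables)
    )
    per_member: list[dict[str, float]] = []
    for m_idx, member in enumerate(ensemble.members):
        base = member.predict(reference)
        vi: dict[str, float] = {}
        if np.std(base) < 1e-12:  # constant output: depends on nothing
            per_member.append({v: 0.0 for v in variables})
            continue
        for var in variables:
            if var not in member.predictor_set.variables:
                vi[var] = 0.0
                continue
            rs = []
            for p in range(n_perm):
                rng = np.random.default_rng(
                    derive_seed(seed, "vi", m_idx, var, p)
                )
                shuffled = reference.copy()
                shuffled[var] = rng.permutation(shuffled[var].to_numpy())
                perm_pred = member.predict(shuffled)
                if np.std(perm_pred) < 1e-12:
                    rs.append(0.0)
                else:
                    rs.append(pearsonr(base, perm_pred)[0])
            vi[var] = float(max(0.0, 1.0 - np.mean(rs)))
        per_member.append(vi)
    return {
        v: float(np.mean([vi[v] for vi in per_member])) for v in variables
    }


def member_tss_table(members: Sequence[FittedModel]) -> pd.DataFrame:
    """Long table of member evaluations (feeds the per-set mean TSS summary)."""
    rows = []
    for m in members:
        rows.append(
            {
                "predictor_set": m.predictor_set.id,
                "algorithm": m.algorithm,
                "pa_draw": m.pa_draw,
                "split": m.split,
                "tss": m.tss_eval,
                "sensitivity": m.evaluation.sensitivity,
                "specificity": m.evaluation.specificity,
                "status": m.status,
            }
        )
    return pd.DataFrame(rows)
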