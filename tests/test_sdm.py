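"""TSS evaluation, maxTSS thresholding, splits, battery, ensemble, VI."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmsens import (
    STANDARD_PREDICTOR_SETS,
    EnsembleModel,
    Evaluation,
    FittedModel,
    PredictorSet,
    SDMConfig,
    build_ensemble,
    check_collinearity,
    evaluate_tss,
    fit_battery,
    max_tss_threshold,
    split_data,
    variable_importance,
)


def brute_force_max_tss(scores, labels):
    """Independent oracle: exhaustive search over all candidate thresholds."""
    uniq = np.unique(scores)
    cands = np.concatenate(
        ([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1])
    )
    return max(evaluate_tss(scores, labels, t).tss for t in cands)


class TestEvaluateTss:
    def test_perfect_separation_gives_tss_one(self):
        ev = evaluate_tss([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert ev.sensitivity == 1 and ev.specificity == 1 and ev.tss == 1

    def test_all_positive_classifier(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.2, 0.9, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        ev = evaluate_tss(scores, labels, 0.0)
        assert ev.sensitivity == 1 and ev.specificity == 0 and ev.tss == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_tss([0.1, 0.9], [1, 1], 0.5)

    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.05, 0.95),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_identity_holds_on_random_confusions(self, seed, threshold):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 1, 60)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, 58)])
        ev = evaluate_tss(scores, labels, threshold)
        assert abs(ev.tss - (ev.sensitivity + ev.specificity - 1)) < 1e-12


class TestMaxTss:
    def test_midpoint_rule_on_separated_toy(self):
        assert max_tss_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1]) == 0.5

    def test_realisable_optimum_reached(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 80)
        labels = (scores >= 0.5).astype(int)
        thr = max_tss_threshold(scores, labels)
        assert evaluate_tss(scores, labels, thr).tss == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = np.round(rng.uniform(0, 1, n), 2)  # ties likely
        labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
        thr = max_tss_threshold(scores, labels)
        assert evaluate_tss(scores, labels, thr).tss == pytest.approx(
            brute_force_max_tss(scores, labels), abs=1e-12
        )

    def test_tie_breaks_toward_lowest_threshold(self):
        # two optimal plateaus: candidates 0.5 and higher achieve the same
        # TSS; the lowest must be returned
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 0, 1, 1]
        thr = max_tss_threshold(scores, labels)
        assert thr == 0.5


class TestSplitData:
    def test_70_30_counts(self):
        labels = np.array([1] * 100 + [0] * 100)
        train, evl = split_data(labels, 0.7, rep=0, seed=1)
        assert len(train) == 140 and len(evl) == 60
        assert labels[train].sum() == 70 and labels[evl].sum() == 30

    def test_partitions_disjoint_exhaustive(self):
        labels = np.array([1] * 37 + [0] * 23)
        train, evl = split_data(labels, 0.7, rep=2, seed=5)
        assert set(train) | set(evl) == set(range(60))
        assert not (set(train) & set(evl))

    def test_reps_differ_seed_reproduces(self):
        labels = np.array([1] * 30 + [0] * 30)
        t1, _ = split_data(labels, 0.7, rep=1, seed=9)
        t1b, _ = split_data(labels, 0.7, rep=1, seed=9)
        t2, _ = split_data(labels, 0.7, rep=2, seed=9)
        assert (t1 == t1b).all()
        assert not np.array_equal(t1, t2)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_data([1, 1, 1, 1, 1, 0, 0, 0, 0, 1], 0.7)  # 4 zeros


def _separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    pres = pd.DataFrame({"A": rng.normal(3, 0.3, n), "B": rng.normal(0, 1, n)})
    pa = pd.DataFrame({"A": rng.normal(-3, 0.3, n), "B": rng.normal(0, 1, n)})
    return pres, pa


class TestBattery:
    def test_member_count_matches_design(self):
        pres, pa = _separable_data()
        pset = PredictorSet("ps", ("A", "B"))
        cfg = SDMConfig(
            algorithms=("glm", "gam", "rf", "brt"),
            n_splits=3,
            rf_trees=20,
            brt_trees=20,
        )
        members = fit_battery(pres, [pa] * 5, pset, cfg, seed=0)
        assert len(members) == 4 * 3 * 5  # 60 members at the full design

    def test_degenerate_config_single_member(self):
        pres, pa = _separable_data()
        cfg = SDMConfig(algorithms=("glm",), n_splits=1)
        members = fit_battery(pres, [pa], PredictorSet("p", ("A",)), cfg, 1)
        assert len(members) == 1

    def test_separable_classes_reach_tss_one(self):
        pres, pa = _separable_data()
        cfg = SDMConfig(algorithms=("glm", "rf"), n_splits=2, rf_trees=50)
        members = fit_battery(pres, [pa], PredictorSet("p", ("A",)), cfg, 2)
        assert all(m.status == "ok" for m in members)
        assert all(m.tss_eval == 1.0 for m in members)


class _StubEstimator:
    """Deterministic probability model for ensemble arithmetic tests."""

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, X):
        p = np.clip(self.fn(np.asarray(X, dtype=float)), 0, 1)
        return np.column_stack([1 - p, p])


def _stub_member(fn, tss, pset):
    return FittedModel(
        algorithm="stub",
        predictor_set=pset,
        pa_draw=0,
        split=0,
        estimator=_StubEstimator(fn),
        threshold=0.5,
        tss_eval=tss,
        evaluation=Evaluation(1.0, tss),
        seed=0,
    )


class TestEnsemble:
    pset = PredictorSet("p", ("A",))

    def _data(self):
        data = pd.DataFrame({"A": np.linspace(-1, 1, 40)})
        labels = (data["A"] > 0).astype(int).to_numpy()
        return data, labels

    def test_all_weak_members_fail_ensemble(self):
        data, labels = self._data()
        members = [
            _stub_member(lambda X: (X[:, 0] > 0) * 1.0, 0.3, self.pset),
            _stub_member(lambda X: (X[:, 0] > 0) * 1.0, 0.5, self.pset),  # not > 0.5
        ]
        ens = build_ensemble(members, data, labels, compute_importance=False)
        assert ens.failed

    def test_mean_combination_rule(self):
        data, labels = self._data()
        members = [
            _stub_member(lambda X: np.full(len(X), 0.2), 0.8, self.pset),
            _stub_member(lambda X: np.full(len(X), 0.8), 0.8, self.pset),
        ]
        ens = build_ensemble(members, data, labels, compute_importance=False)
        np.testing.assert_allclose(ens.predict(data), 0.5)

    def test_singleton_committee_reproduces_member(self):
        data, labels = self._data()
        fn = lambda X: 1 / (1 + np.exp(-4 * X[:, 0]))
        members = [
            _stub_member(fn, 0.9, self.pset),
            _stub_member(lambda X: np.full(len(X), 0.5), 0.2, self.pset),
        ]
        ens = build_ensemble(members, data, labels, compute_importance=False)
        assert len(ens.members) == 1
        np.testing.assert_allclose(ens.predict(data), fn(data.to_numpy()))

    def test_ensemble_score_within_member_range(self):
        data, labels = self._data()
        fns = [
            lambda X: 1 / (1 + np.exp(-3 * X[:, 0])),
            lambda X: 0.5 + 0.4 * np.tanh(X[:, 0]),
            lambda X: (X[:, 0] > 0.2) * 0.9,
        ]
        members = [_stub_member(f, 0.9, self.pset) for f in fns]
        ens = build_ensemble(members, data, labels, compute_importance=False)
        scores = np.stack([m.predict(data) for m in members])
        e = ens.predict(data)
        assert (e >= scores.min(axis=0) - 1e-12).all()
        assert (e <= scores.max(axis=0) + 1e-12).all()


class TestVariableImportance:
    def test_unused_variable_scores_zero(self):
        pset = PredictorSet("p", ("A",))
        member = _stub_member(lambda X: 1 / (1 + np.exp(-X[:, 0])), 0.9, pset)
        ens = EnsembleModel(predictor_set=pset, members=[member])
        rng = np.random.default_rng(0)
        ref = pd.DataFrame({"A": rng.normal(0, 2, 200), "Z": rng.normal(0, 1, 200)})
        vi = variable_importance(ens, ref, n_perm=5, seed=1, variables=["A", "Z"])
        assert vi["Z"] == 0.0
        assert vi["A"] > 0.5

    def test_constant_model_all_zero(self):
        pset = PredictorSet("p", ("A", "B"))
        member = _stub_member(lambda X: np.full(len(X), 0.7), 0.9, pset)
        ens = EnsembleModel(predictor_set=pset, members=[member])
        rng = np.random.default_rng(0)
        ref = pd.DataFrame({"A": rng.normal(size=100), "B": rng.normal(size=100)})
        vi = variable_importance(ens, ref, n_perm=3, seed=0)
        assert vi == {"A": 0.0, "B": 0.0}


def test_seven_standard_predictor_sets_shipped():
    assert len(STANDARD_PREDICTOR_SETS) == 7
    for p in STANDARD_PREDICTOR_SETS.values():
        assert len(p.variables) == 4
        assert "BIO12" in p.variables and "BIO15" in p.variables


def test_collinearity_preflight_warns_not_errors(small_stack):
    # A and B are correlated at 0.8 on the small domain
    pset = PredictorSet("ab", ("A", "B"))
    with pytest.warns(UserWarning, match="correlated"):
        offenders = check_collinearity(pset, small_stack)
    assert offenders and abs(offenders[0][2]) >= 0.7
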