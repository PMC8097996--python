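"""Weighted forest: ensembling, likelihood, weight learning, lambda CV."""

import numpy as np
import pytest

from rwsurf import (
    RWRSFConfig,
    SurvivalData,
    ensemble_negloglik,
    fit_forest,
    fit_rwrsf,
    grow_tree,
    learn_weights,
    predict,
    predict_tree_chf,
    select_lambda,
)
from rwsurf.forest import ForestModel, _likelihood_arrays, _negloglik, project_simplex

from conftest import weibull_ph_data


def single_leaf_forest(times, events, n_copies=1):
    """Forest of identical single-leaf trees built from the given records."""
    data = SurvivalData(times, events, np.zeros((len(times), 1)), ["x"])
    tree = grow_tree(data, max_depth=0, rng=np.random.default_rng(0))
    n = len(times)
    return ForestModel(
        trees=[tree] * n_copies,
        inbag=[np.arange(n)] * n_copies,
        weights=np.full(n_copies, 1.0 / n_copies),
        lambda_reg=0.0,
        grid=np.unique(data.time[data.event == 1]),
        feature_names=["x"],
        n_train=n,
        seed=0,
    ), data


def two_tree_forest(seed=0):
    """Two distinct trees over the same records, assembled by hand."""
    data = weibull_ph_data(80, seed=seed, beta=1.2, n_noise=1)
    signal_only = SurvivalData(data.time, data.event,
                               np.column_stack([data.X[:, 0], np.zeros(len(data))]),
                               data.feature_names)
    noise_only = SurvivalData(data.time, data.event,
                              np.column_stack([np.zeros(len(data)), data.X[:, 1]]),
                              data.feature_names)
    t_signal = grow_tree(signal_only, mtry=2, rng=np.random.default_rng(1))
    t_noise = grow_tree(noise_only, mtry=2, rng=np.random.default_rng(2))
    forest = ForestModel(
        trees=[t_signal, t_noise],
        inbag=[np.arange(len(data))] * 2,
        weights=np.array([0.5, 0.5]),
        lambda_reg=0.0,
        grid=np.unique(data.time[data.event == 1]),
        feature_names=data.feature_names,
        n_train=len(data),
        seed=0,
    )
    return forest, data


class TestFitPredict:
    def test_single_tree_forest_equals_tree(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=1, seed=5)
        x = small_signal_data.X[3]
        tree_chf = predict_tree_chf(forest.trees[0], x)
        pred = predict(forest, x)
        np.testing.assert_allclose(pred.chf[0], tree_chf(forest.grid), atol=1e-14)

    def test_fixed_seed_reproduces_forest(self, small_signal_data):
        f1 = fit_forest(small_signal_data, n_trees=8, seed=9)
        f2 = fit_forest(small_signal_data, n_trees=8, seed=9)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert t1.to_dict() == t2.to_dict()
        np.testing.assert_array_equal(f1.inbag[3], f2.inbag[3])

    def test_uniform_weights_equal_plain_average(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=12, seed=2)
        X = small_signal_data.X[:20]
        manual = np.zeros((len(X), len(forest.grid)))
        for b, tree in enumerate(forest.trees):
            manual += forest.leaf_table(b)[tree.apply(X)]
        manual /= forest.n_trees
        pred = predict(forest, X)  # weights are uniform after fit
        np.testing.assert_allclose(pred.chf, manual, rtol=0, atol=1e-12)

    def test_vertex_weights_select_single_tree(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=4, seed=3)
        w = np.array([1.0, 0.0, 0.0, 0.0])
        x = small_signal_data.X[0]
        pred = predict(forest, x, weights=w)
        np.testing.assert_allclose(pred.chf[0], predict_tree_chf(forest.trees[0], x)(forest.grid))

    def test_identical_trees_make_weights_irrelevant(self):
        forest, data = single_leaf_forest([1.0, 2.0, 3.0], [1, 1, 1], n_copies=4)
        x = np.zeros(1)
        for w in ([1, 0, 0, 0], [0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4]):
            pred = predict(forest, x, weights=np.asarray(w, float))
            np.testing.assert_allclose(pred.chf[0], [1 / 3, 5 / 6, 11 / 6])

    def test_survival_and_mortality_invariants(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=10, seed=1)
        pred = predict(forest, small_signal_data.X)
        assert np.all(pred.mortality >= 0)
        assert np.all(np.diff(pred.survival, axis=1) <= 1e-12)
        assert np.all(pred.survival <= 1.0 + 1e-12)


class TestNegloglik:
    def test_hand_computed_three_record_fixture(self):
        forest, data = single_leaf_forest([1.0, 2.0, 3.0], [1, 1, 1])
        eps = 1e-12
        # NA increments: 1/3 at t=1, 1/2 at t=2, 1 at t=3; levels 1/3, 5/6, 11/6
        expected = np.mean([
            -np.log(1 / 3 + eps) + 1 / 3,
            -np.log(1 / 2 + eps) + 5 / 6,
            -np.log(1.0 + eps) + 11 / 6,
        ])
        assert ensemble_negloglik(forest, data, np.array([1.0])) == pytest.approx(expected, abs=1e-10)

    def test_all_censored_loss_is_mean_hazard(self):
        # leaf grown on one event + censorings, evaluated on censored records
        forest, _ = single_leaf_forest([1.0, 2.0, 3.0], [1, 0, 0])
        censored = SurvivalData([1.5, 2.5], [0, 0], np.zeros((2, 1)), ["x"])
        # H(1.5) = H(2.5) = 1/3 (single event at t=1 with Y=3)
        assert ensemble_negloglik(forest, censored, np.array([1.0])) == pytest.approx(1 / 3)

    def test_rejects_off_simplex_weights(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=3, seed=0)
        with pytest.raises(ValueError):
            ensemble_negloglik(forest, small_signal_data, np.array([0.7, 0.7, -0.4]))


class TestLearnWeights:
    def test_huge_lambda_forces_uniform(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=10, seed=4)
        w = learn_weights(forest, small_signal_data, 1e6)
        np.testing.assert_allclose(w, 0.1, atol=1e-3)

    def test_identical_trees_tie_broken_to_uniform(self):
        forest, data = single_leaf_forest([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], n_copies=5)
        w = learn_weights(forest, data, 0.5)
        np.testing.assert_allclose(w, 0.2, atol=1e-6)

    def test_two_tree_grid_search_oracle(self):
        forest, data = two_tree_forest(seed=21)
        w = learn_weights(forest, data, 0.0)
        grid = np.arange(0.0, 1.0001, 0.01)
        losses = [ensemble_negloglik(forest, data, np.array([g, 1 - g])) for g in grid]
        w1_grid = grid[int(np.argmin(losses))]
        assert abs(w[0] - w1_grid) <= 0.02

    def test_signal_tree_outweighs_noise_tree(self):
        forest, data = two_tree_forest(seed=33)
        w = learn_weights(forest, data, 0.0)
        assert w[0] > w[1]

    def test_objective_never_worse_than_uniform(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=15, seed=6)
        for lam in (0.0, 0.01, 1.0):
            w = learn_weights(forest, small_signal_data, lam)
            obj = ensemble_negloglik(forest, small_signal_data, w) + lam * w @ w
            uni = np.full(15, 1 / 15)
            obj_uni = ensemble_negloglik(forest, small_signal_data, uni) + lam * uni @ uni
            assert obj <= obj_uni + 1e-9
            assert w.min() >= -1e-12 and w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_cox_loss_alternative_runs(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=6, seed=7)
        w = learn_weights(forest, small_signal_data, 0.1, loss="cox")
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert w.min() >= -1e-12


class TestSelectLambda:
    def test_singleton_grid_returned(self, small_signal_data):
        forest = fit_forest(small_signal_data, n_trees=5, seed=1)
        assert select_lambda(forest, small_signal_data, [0.37], seed=0) == 0.37

    def test_ties_favor_larger_lambda(self):
        # identical trees: every lambda yields the same held-out loss
        forest, data = single_leaf_forest(
            np.arange(1.0, 21.0), np.r_[np.ones(15, int), np.zeros(5, int)], n_copies=3)
        assert select_lambda(forest, data, [0.0, 1e6], n_folds=2, seed=0) == 1e6


class TestFitRwrsf:
    def test_end_to_end_simplex_weights(self, small_signal_data):
        model = fit_rwrsf(small_signal_data, RWRSFConfig(n_trees=20, seed=0))
        assert model.weights.min() >= -1e-12
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert model.lambda_reg in RWRSFConfig().lambda_grid

    def test_forced_huge_lambda_matches_unweighted_rsf(self, small_signal_data):
        model = fit_rwrsf(small_signal_data, RWRSFConfig(n_trees=10, seed=0, lambda_reg=1e6))
        plain = fit_forest(small_signal_data, n_trees=10, seed=0)
        X = small_signal_data.X[:15]
        np.testing.assert_allclose(predict(model, X).chf, predict(plain, X).chf, atol=1e-6)

    def test_json_roundtrip_preserves_predictions(self, tmp_path, small_signal_data):
        model = fit_rwrsf(small_signal_data, RWRSFConfig(n_trees=6, seed=2))
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = ForestModel.from_json(path)
        X = small_signal_data.X[:10]
        np.testing.assert_allclose(predict(model, X).mortality, predict(clone, X).mortality, atol=1e-12)


def test_simplex_projection_properties():
    rng = np.random.default_rng(0)
    for _ in range(50):
        v = rng.normal(scale=3.0, size=rng.integers(2, 12))
        w = project_simplex(v)
        assert w.min() >= 0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # projection of a simplex point is itself
        np.testing.assert_allclose(project_simplex(w), w, atol=1e-12)
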