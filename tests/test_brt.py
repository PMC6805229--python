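"""Boosted regression trees: fitting, influence, response curves, metrics."""

import numpy as np
import pandas as pd
import pytest

from diatom_ntrans.brt import (
    BRTConfig,
    BRTModel,
    _best_split,
    _grow_tree,
    _Tree,
    bernoulli_deviance,
    cv_auc,
    evaluate,
    fit_brt,
    laplace_deviance,
    partial_dependence,
    relative_influence,
    simplify,
)
from _oracles import auc_pair_count


def _toy_regression(seed=0, n=300, n_noise=8, noise_sd=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, n_noise + 1)),
                     columns=["temperature"] + [f"noise{i}" for i in range(n_noise)])
    y = 1.0 / (1.0 + np.exp(-2.0 * X["temperature"])) \
        + rng.normal(0, noise_sd, n)
    return X, pd.Series(y)


FAST = dict(learning_rate=0.01, max_trees=400, tree_block=50,
            n_folds=5, patience_blocks=3)


def _brute_best_split(X, z, idx, min_obs):
    """Reference split search: try every (variable, midpoint) candidate."""
    best = (-1, 0.0, 0.0)
    n = len(idx)
    parent = z[idx].sum() ** 2 / n
    for j in range(X.shape[1]):
        xs = np.unique(X[idx, j])
        for a, b in zip(xs[:-1], xs[1:]):
            t = 0.5 * (a + b)
            left = idx[X[idx, j] <= t]
            right = idx[X[idx, j] > t]
            if len(left) < min_obs or len(right) < min_obs:
                continue
            imp = (z[left].sum() ** 2 / len(left)
                   + z[right].sum() ** 2 / len(right) - parent)
            if imp > best[2] + 1e-12:
                best = (j, t, imp)
    return best


class TestSplitSearch:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = np.ascontiguousarray(rng.normal(size=(60, 4)))
        z = rng.normal(size=60)
        idx = np.arange(60)
        got = _best_split(X, z, idx, 5)
        want = _brute_best_split(X, z, idx, 5)
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1])
        assert got[2] == pytest.approx(want[2])

    def test_tree_respects_leaf_budget(self):
        rng = np.random.default_rng(1)
        X = np.ascontiguousarray(rng.normal(size=(200, 3)))
        z = rng.normal(size=200)
        tree, members, splits = _grow_tree(X, z, np.arange(200), 6, 10)
        assert len(members) <= 6                 # terminal nodes
        assert len(splits) == len(members) - 1
        assert all(len(m) >= 10 for m in members.values())


class TestFit:
    def test_constant_response_degenerate(self):
        X = pd.DataFrame({"a": np.linspace(0, 1, 40)})
        with pytest.warns(UserWarning, match="constant"):
            m = fit_brt(X, np.full(40, 3.3),
                        BRTConfig(loss="laplace", **FAST))
        assert m.n_trees == 0
        assert m.predict(X) == pytest.approx(3.3)

    def test_separable_binary_high_cv_auc(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=200),
                          "junk": rng.normal(size=200)})
        y = (X["x"] > 0.2).astype(float)
        m = fit_brt(X, y, BRTConfig(loss="bernoulli", seed=1, **FAST))
        assert evaluate(m, X, y)["auc"] >= 0.95

    def test_bit_reproducible(self):
        X, y = _toy_regression(3, n=120, n_noise=3)
        cfg = BRTConfig(loss="laplace", seed=9, **FAST)
        m1 = fit_brt(X, y, cfg)
        m2 = fit_brt(X, y, BRTConfig(loss="laplace", seed=9, **FAST))
        assert m1.n_trees == m2.n_trees
        assert np.array_equal(m1.predict(X), m2.predict(X))
        pd.testing.assert_frame_equal(m1.cv_profile, m2.cv_profile)

    def test_training_deviance_monotone(self):
        X, y = _toy_regression(5, n=150, n_noise=3)
        m = fit_brt(X, y, BRTConfig(loss="laplace", seed=2, **FAST))
        assert (np.diff(m.train_deviance) <= 1e-12).all()
        yb = (y > y.median()).astype(float)
        mb = fit_brt(X, yb, BRTConfig(loss="bernoulli", seed=2, **FAST))
        assert (np.diff(mb.train_deviance) <= 1e-12).all()

    def test_missing_rows_excluded_and_counted(self):
        X, y = _toy_regression(1, n=120, n_noise=2)
        X.iloc[3, 0] = np.nan
        X.iloc[7, 1] = np.nan
        m = fit_brt(X, y, BRTConfig(loss="laplace", **FAST))
        assert m.n_excluded == 2
        assert len(m.train_index) == 118

    def test_shrinkage_runs_converge(self):
        """Halving the learning rate while doubling the trees changes the
        final training deviance by less than 1% (the boosting path
        converges as the step size shrinks)."""
        from diatom_ntrans.brt import _Booster
        X, y = _toy_regression(11, n=150, n_noise=2)
        Xm, ym = X.to_numpy(), y.to_numpy()
        devs = []
        for lr, n_trees in ((0.02, 1000), (0.01, 2000)):
            cfg = BRTConfig(loss="laplace", learning_rate=lr, seed=4)
            booster = _Booster(Xm, ym, cfg, np.random.default_rng(4))
            booster.grow(n_trees)
            devs.append(booster.deviance())
        assert abs(devs[0] - devs[1]) / devs[0] < 0.01

    def test_nonbinary_bernoulli_rejected(self):
        X = pd.DataFrame({"a": np.arange(25.0)})
        with pytest.raises(ValueError, match="binary"):
            fit_brt(X, np.linspace(0, 2, 25), BRTConfig(loss="bernoulli", **FAST))


class TestInfluence:
    def test_sums_to_100(self):
        X, y = _toy_regression(0, n=200, n_noise=4)
        m = fit_brt(X, y, BRTConfig(loss="laplace", **FAST))
        infl = relative_influence(m)
        assert infl.sum() == pytest.approx(100.0, abs=1e-6)
        assert (infl >= 0).all()

    def test_single_informative_variable_takes_all(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=200),
                          "c": np.zeros(200)})    # constant: unsplittable
        y = (X["x"] > 0).astype(float) * 2.0 + rng.normal(0, 0.01, 200)
        m = fit_brt(X, y, BRTConfig(loss="laplace", **FAST))
        infl = relative_influence(m)
        assert infl["x"] == pytest.approx(100.0)
        assert infl["c"] == 0.0

    def test_zero_split_model_flagged(self):
        X = pd.DataFrame({"a": np.linspace(0, 1, 40)})
        with pytest.warns(UserWarning):
            m = fit_brt(X, np.full(40, 1.0), BRTConfig(loss="laplace", **FAST))
        infl = relative_influence(m)
        assert (infl == 0).all()
        assert infl.attrs["no_splits"]

    def test_planted_driver_ranks_first(self):
        X, y = _toy_regression(7)
        cfg = BRTConfig(loss="laplace", learning_rate=0.01, max_trees=600,
                        tree_block=50, n_folds=5, seed=7)
        m = fit_brt(X, y, cfg)
        assert relative_influence(m).index[0] == "temperature"

    def test_permuted_response_spreads_influence(self):
        """With y shuffled, no variable averages above 3x the uniform
        share of influence across seeds."""
        X, y = _toy_regression(0, n=100, n_noise=5, noise_sd=0.5)
        totals = np.zeros(X.shape[1])
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            cfg = BRTConfig(loss="laplace", learning_rate=0.02, max_trees=150,
                            tree_block=50, n_folds=5, patience_blocks=2,
                            seed=seed)
            totals += relative_influence(fit_brt(X, yp, cfg)).reindex(
                X.columns).to_numpy()
        mean_infl = totals / n_seeds
        assert mean_infl.max() < 3.0 * (100.0 / X.shape[1])


def _hand_ensemble():
    """Two hand-built trees over features (x0, x1), plus intercept 0.5.

    tree A: split x0 at 0.5 -> -0.2 / +0.4
    tree B: root split x1 at 0.0 -> left leaf -0.1;
            right: split x0 at 1.5 -> +0.1 / +0.3
    """
    tree_a = _Tree(np.array([0, -1, -1]), np.array([0.5, 0, 0]),
                   np.array([1, -1, -1]), np.array([2, -1, -1]),
                   np.array([0.0, -0.2, 0.4]))
    tree_b = _Tree(np.array([1, -1, 0, -1, -1]),
                   np.array([0.0, 0.0, 1.5, 0.0, 0.0]),
                   np.array([1, -1, 3, -1, -1]),
                   np.array([2, -1, 4, -1, -1]),
                   np.array([0.0, -0.1, 0.0, 0.1, 0.3]))
    return BRTModel(
        config=BRTConfig(loss="laplace"), feature_names=["x0", "x1"],
        init=0.5, trees=[tree_a, tree_b], influence_raw=np.array([3.0, 1.0]),
        n_trees=2, cv_profile=pd.DataFrame(), cv_heldout=None,
        train_index=pd.Index([]), train_deviance=np.empty(0))


class TestPartialDependence:
    def test_hand_built_ensemble_matches_clamped_average(self):
        model = _hand_ensemble()
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1.2, size=(40, 2)), columns=["x0", "x1"])
        grid = np.linspace(-2, 3, 21)
        curve = partial_dependence(model, X, "x0", grid=grid)
        for g, got in zip(grid, curve.to_numpy()):
            Xc = X.copy()
            Xc["x0"] = g
            expected = model.predict_link(Xc).mean()
            assert got == pytest.approx(expected)

    def test_single_split_tree_is_step_function(self):
        model = _hand_ensemble()
        model.trees = model.trees[:1]
        model.n_trees = 1
        X = pd.DataFrame({"x0": np.linspace(-1, 2, 30), "x1": np.zeros(30)})
        curve = partial_dependence(model, X, "x0", grid=np.array([0.0, 1.0]))
        assert curve.iloc[0] == pytest.approx(0.5 - 0.2)
        assert curve.iloc[1] == pytest.approx(0.5 + 0.4)

    def test_unused_variable_flat_curve(self):
        model = _hand_ensemble()
        model.trees = model.trees[:1]   # tree A ignores x1
        model.n_trees = 1
        X = pd.DataFrame({"x0": np.linspace(-1, 2, 10), "x1": np.zeros(10)})
        curve = partial_dependence(model, X, "x1", grid=np.linspace(-3, 3, 7))
        assert np.ptp(curve.to_numpy()) == 0.0

    def test_empty_grid_rejected(self):
        model = _hand_ensemble()
        X = pd.DataFrame({"x0": [0.0], "x1": [0.0]})
        with pytest.raises(ValueError, match="grid"):
            partial_dependence(model, X, "x0", grid=np.array([]))


class TestSimplify:
    def test_single_predictor_unchanged(self):
        X, y = _toy_regression(0, n=100, n_noise=0)
        cfg = BRTConfig(loss="laplace", **FAST)
        m = fit_brt(X, y, cfg)
        reduced, dropped = simplify(m, X, y, cfg)
        assert dropped == []
        assert reduced.feature_names == ["temperature"]

    def test_noise_predictors_dropped_before_driver(self):
        X, y = _toy_regression(4, n=200, n_noise=3)
        cfg = BRTConfig(loss="laplace", learning_rate=0.02, max_trees=300,
                        tree_block=50, n_folds=5, patience_blocks=2, seed=4)
        m = fit_brt(X, y, cfg)
        reduced, dropped = simplify(m, X, y, cfg)
        assert "temperature" in reduced.feature_names
        assert len(dropped) < X.shape[1]


class TestEvaluate:
    def test_auc_extremes(self):
        y = np.array([0, 0, 1, 1, 1.0])
        assert cv_auc(y, y) == 1.0
        assert cv_auc(y, -y) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_matches_exhaustive_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 30)
        y = rng.integers(0, 2, n).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        score = np.round(rng.normal(size=n), 1)   # induce ties
        assert cv_auc(y, score) == pytest.approx(auc_pair_count(y, score))

    def test_laplace_quartile_correlation_passes_on_signal(self):
        X, y = _toy_regression(6, n=200, n_noise=2)
        m = fit_brt(X, y, BRTConfig(loss="laplace", seed=6, **FAST))
        res = evaluate(m, X, y)
        assert res["cross_validated"]
        assert res["passes"]
        assert abs(res["r"]) > 0.35 and res["p"] < 0.05

    def test_single_class_auc_undefined(self):
        assert np.isnan(cv_auc(np.ones(5), np.arange(5.0)))
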