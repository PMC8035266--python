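import itertools

import numpy as np
import pandas as pd
import pytest

from pneumotyper.core_io import ValidationError
from pneumotyper.host_model import (
    ForestSpec,
    boruta_select,
    fit_forest,
    importance_intervals,
    linear_aic,
    median_normalize_expression,
    per_tree_importance,
    stepwise_aic_fit,
    tune_forest,
    z_importance,
)


class TestMedianNormalize:
    def test_arithmetic_and_single_state(self):
        med = pd.DataFrame(
            {"s1": [2.0, 5.0], "s2": [4.0], "s3": [8.0], "s4": [6.0]},
            index=["g1"],
        ) if False else pd.DataFrame(
            [[2.0, 4.0, 8.0, 6.0]], index=["g1"], columns=list("abcd")
        )
        out = median_normalize_expression(med)
        assert np.allclose(out.loc["g1"], [0.25, 0.5, 1.0, 0.75])
        single = median_normalize_expression(pd.DataFrame([[3.0]], index=["g"]))
        assert single.iloc[0, 0] == 1.0

    def test_scale_invariance_and_nonpositive_flagged(self):
        med = pd.DataFrame([[2.0, 4.0]], index=["g"], columns=["a", "b"])
        out1 = median_normalize_expression(med)
        out2 = median_normalize_expression(med * 7.0)
        pd.testing.assert_frame_equal(out1, out2)
        with pytest.warns(UserWarning, match="non-positive"):
            bad = median_normalize_expression(
                pd.DataFrame([[-1.0, -2.0]], index=["g"], columns=["a", "b"])
            )
        assert bad.isna().all().all()


class TestForestLearner:
    def test_chance_level_on_shuffled_labels(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(160, 8))
        y = np.repeat(np.arange(4), 40)
        rng.shuffle(y)
        spec = ForestSpec(task="classification", ntrees=150, cv_folds=4,
                          cv_repeats=2, seed=1)
        best, trace = tune_forest(X, y, spec, mtry_grid=[2], ntrees_grid=[150])
        assert trace["accuracy"].iloc[0] == pytest.approx(0.25, abs=0.06)

    def test_regression_recovers_planted_signal(self):
        rng = np.random.default_rng(1)
        n = 300
        X = rng.normal(size=(n, 5))
        y = 3.0 * X[:, 0] + rng.normal(scale=1.0, size=n)  # SNR 3
        spec = ForestSpec(task="regression", ntrees=200, cv_folds=5,
                          cv_repeats=1, seed=2)
        best, trace = tune_forest(X, y, spec, mtry_grid=[2, 5],
                                  ntrees_grid=[200])
        assert trace["r2"].max() >= 0.7

    def test_tuning_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] > 0).astype(int)
        spec = ForestSpec(task="classification", ntrees=100, cv_folds=4,
                          cv_repeats=1, seed=3)
        _, t1 = tune_forest(X, y, spec, mtry_grid=[2], ntrees_grid=[100])
        _, t2 = tune_forest(X, y, spec, mtry_grid=[2], ntrees_grid=[100])
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_class_gives_guidance(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 10 + [1] * 2)
        spec = ForestSpec(task="classification", ntrees=100, cv_folds=10)
        with pytest.raises(ValidationError, match="cv_folds"):
            tune_forest(X, y, spec)

    def test_importance_separates_signal_from_noise(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        y = (X[:, 0] + 0.1 * rng.normal(size=200) > 0).astype(int)
        spec = ForestSpec(task="classification", ntrees=200, seed=4)
        model = fit_forest(X, y, spec)
        z = z_importance(per_tree_importance(model, X, y, seed=5))
        assert z[0] > 3 * max(abs(z[1:]))


class TestBoruta:
    def test_planted_features_confirmed_noise_rejected(self):
        rng = np.random.default_rng(5)
        n = 150
        states = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 12))
        X[:, 0] += 1.5 * states
        X[:, 1] -= 1.5 * states
        spec = ForestSpec(task="classification", ntrees=150, seed=6)
        rep = boruta_select(X, states, spec, alpha=0.01, max_iter=25, seed=7)
        assert rep.decisions["x0"] == "Confirmed"
        assert rep.decisions["x1"] == "Confirmed"
        noise_confirmed = [
            f for f, d in rep.decisions.items()
            if d == "Confirmed" and f not in ("x0", "x1")
        ]
        assert not noise_confirmed
        assert set(rep.decisions) == {f"x{i}" for i in range(12)}

    def test_duplicated_feature_shares_decision(self):
        rng = np.random.default_rng(6)
        n = 120
        states = rng.integers(0, 2, size=n)
        base = rng.normal(size=(n, 4))
        base[:, 0] += 1.5 * states
        X = np.hstack([base, base[:, :1]])  # duplicate the informative column
        spec = ForestSpec(task="classification", ntrees=150, seed=8)
        rep = boruta_select(X, states, spec, alpha=0.01, max_iter=20, seed=9)
        assert rep.decisions["x0"] == rep.decisions["x4"] == "Confirmed"

    def test_underpowered_max_iter_rejected(self):
        with pytest.raises(ValidationError, match="under-powered"):
            boruta_select(np.zeros((10, 2)), np.zeros(10),
                          ForestSpec(ntrees=100), max_iter=5)


class TestImportanceIntervals:
    def test_constant_feature_interval_contains_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 4))
        X[:, 3] = 1.0  # constant
        y = (X[:, 0] > 0).astype(int)
        spec = ForestSpec(task="classification", ntrees=150, seed=10)
        ivals, summary = importance_intervals(X, y, spec, n_refits=10,
                                              level=0.9, seed=11)
        by = {iv.feature: iv for iv in ivals}
        assert by["x3"].lower <= 0.0 <= by["x3"].upper + 1e-9
        assert by["x0"].lower > by["x3"].upper
        assert 0 <= summary["oob_accuracy"] <= 1

    def test_intervals_nest_as_level_increases(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        spec = ForestSpec(task="classification", ntrees=120, seed=12)
        narrow, _ = importance_intervals(X, y, spec, n_refits=12, level=0.5,
                                         seed=13)
        wide, _ = importance_intervals(X, y, spec, n_refits=12, level=0.99,
                                       seed=13)
        for a, b in zip(narrow, wide):
            assert b.lower <= a.lower + 1e-12 and a.upper <= b.upper + 1e-12


def brute_force_best_subset_aic(X, y):
    n, p = X.shape
    best = (np.inf, ())
    for r in range(p + 1):
        for subset in itertools.combinations(range(p), r):
            design = np.hstack([np.ones((n, 1)), X[:, list(subset)]])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(((y - design @ beta) ** 2).sum())
            aic = linear_aic(rss, n, len(subset))
            if aic < best[0] - 1e-12:
                best = (aic, subset)
    return best


class TestStepwiseAic:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=50)
        X = np.empty((50, 0))
        rep = stepwise_aic_fit(X, y)
        expected = 50 * np.log(np.var(y, ddof=1) * 49 / 50) + 2
        assert rep.aic == pytest.approx(expected, rel=1e-10)
        assert rep.selected == []

    def test_selects_signal_and_drops_noise(self):
        # the true predictor must always enter; a lone noise term may
        # slip in with P(chi2_1 > 2) ~ 0.157 under the AIC penalty
        signal_hits, noise_hits = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            X = rng.normal(size=(n, 2))
            y = 2.0 * X[:, 0] + rng.normal(size=n)
            rep = stepwise_aic_fit(pd.DataFrame(X, columns=["x1", "x2"]), y)
            signal_hits += "x1" in rep.selected
            noise_hits += "x2" in rep.selected
        assert signal_hits == 10
        assert noise_hits <= 4

    def test_matches_best_subset_enumeration(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 100, 6
            X = rng.normal(size=(n, p))
            beta = np.array([2.0, -1.5, 0, 0, 0, 0])
            y = X @ beta + rng.normal(size=n)
            rep = stepwise_aic_fit(X, y)
            best_aic, best_subset = brute_force_best_subset_aic(X, y)
            assert rep.aic == pytest.approx(best_aic, rel=1e-10)
            assert tuple(int(s[1:]) for s in rep.selected) == best_subset

    def test_never_worse_than_intercept_only(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)  # pure noise
        rep = stepwise_aic_fit(X, y)
        intercept_aic = linear_aic(float(((y - y.mean()) ** 2).sum()), 60, 0)
        assert rep.aic <= intercept_aic + 1e-10
        assert rep.aic == min(rep.visited_aic)

    def test_unidentifiable_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            stepwise_aic_fit(np.zeros((5, 4)), np.zeros(5))
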