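"""Rolling windows and the two model phases: leakage guards, centering,
stacking, weighting degeneracies and grid-search hygiene."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

import moodcast as mc
from moodcast.config import IdiographicConfig, NomotheticConfig, WeightScheme
from moodcast.exceptions import AlignmentError, ConfigError, WindowSkipped
from moodcast.panel import FeatureCodec
from moodcast.windows import _cv_folds, per_split_candidate_grid

from conftest import make_linear_window_df


@pytest.fixture(scope="module")
def linear_df():
    return make_linear_window_df(n_per_person=30, seed=1)


@pytest.fixture(scope="module")
def codec(linear_df):
    return FeatureCodec().fit(linear_df)


class TestBuildWindow:
    def test_target_before_first_full_window_rejected(self, linear_df):
        with pytest.raises(ConfigError):
            mc.build_window(linear_df, t=10, lookback=24)

    def test_no_training_row_at_or_after_target(self, linear_df):
        for t in (24, 27, 29):
            w = mc.build_window(linear_df, t=t, lookback=24)
            assert (w.training["hour_index"] < t).all()
            assert (w.prediction["hour_index"] == t).all() or w.prediction.empty

    def test_training_size_bounded_by_grid(self, linear_df):
        w = mc.build_window(linear_df, t=24, lookback=24)
        assert len(w.training) <= 2 * 24

    def test_rows_without_outcome_excluded_from_training(self, linear_df):
        df = linear_df.copy()
        df.loc[df["hour_index"] == 5, "mood"] = np.nan
        w = mc.build_window(df, t=24, lookback=24)
        assert not (w.training["hour_index"] == 5).any()

    def test_all_outcomes_missing_gives_skip_signal(self, linear_df):
        df = linear_df.copy()
        df.loc[df["hour_index"] < 24, "mood"] = np.nan
        with pytest.raises(WindowSkipped):
            mc.build_window(df, t=24, lookback=24)


class TestNomothetic:
    def test_constant_outcome_centered_predictions_near_zero(self, linear_df, codec):
        df = linear_df.copy()
        df["mood"] = 42.0
        w = mc.build_window(df, t=24, lookback=24)
        model = mc.fit_nomothetic(w, codec, NomotheticConfig(), seed=0)
        preds = model.predict(w.training)
        assert np.allclose(preds, 0.0, atol=1e-6)

    def test_strong_linear_feature_training_r2_above_09(self, linear_df, codec):
        w = mc.build_window(linear_df, t=28, lookback=24)
        model = mc.fit_nomothetic(w, codec, NomotheticConfig(rounds=200), seed=0)
        y = model.center(w.training)
        yhat = model.predict(w.training)
        r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.9

    def test_predictions_finite_for_all_prediction_rows(self, linear_df, codec):
        w = mc.build_window(linear_df, t=25, lookback=24)
        model = mc.fit_nomothetic(w, codec, NomotheticConfig(), seed=0)
        assert np.isfinite(model.predict(w.prediction)).all()

    def test_unseen_person_gets_cohort_mean_centering(self, linear_df, codec):
        w = mc.build_window(linear_df, t=24, lookback=24)
        model = mc.fit_nomothetic(w, codec, NomotheticConfig(), seed=0)
        stranger = linear_df.iloc[[0]].assign(person_id="pZ", mood=50.0)
        centered = model.center(stranger)
        assert centered[0] == pytest.approx(50.0 - model.cohort_mean)


class TestStacking:
    def test_dimensionality_increases_by_exactly_one(self):
        X = np.zeros((7, 20))
        out = mc.augment_features(X, np.arange(7))
        assert out.shape == (7, 21)

    def test_length_mismatch_is_alignment_error(self):
        with pytest.raises(AlignmentError):
            mc.augment_features(np.zeros((5, 3)), np.arange(4))

    def test_order_independence_of_stacked_content(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        preds = rng.normal(size=10)
        perm = rng.permutation(10)
        direct = mc.augment_features(X, preds)[perm]
        shuffled = mc.augment_features(X[perm], preds[perm])
        np.testing.assert_array_equal(direct, shuffled)


class TestIdiographicWeighting:
    @pytest.fixture(scope="class")
    def design(self):
        rng = np.random.default_rng(3)
        n, p = 80, 6
        X = rng.normal(size=(n, p))
        y = 2 * X[:, 0] + rng.normal(size=n)
        pids = np.array([f"p{i % 4}" for i in range(n)])
        return X, y, pids

    def test_equal_weights_reproduce_pooled_forest_exactly(self, design):
        X, y, pids = design
        cfg = IdiographicConfig(forest_size=50, grid_search=False)
        model = mc.fit_idiographic(X, y, pids, "p1", WeightScheme(1.0, 1.0), cfg, seed=7)
        oracle = RandomForestRegressor(
            n_estimators=50, max_features=model.max_features, random_state=7, n_jobs=1
        ).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), oracle.predict(X))

    def test_zero_other_weight_reproduces_person_only_forest_exactly(self, design):
        X, y, pids = design
        cfg = IdiographicConfig(forest_size=50, grid_search=False)
        model = mc.fit_idiographic(X, y, pids, "p1", WeightScheme(1.0, 0.0), cfg, seed=7)
        sel = pids == "p1"
        oracle = RandomForestRegressor(
            n_estimators=50, max_features=model.max_features, random_state=7, n_jobs=1
        ).fit(X[sel], y[sel])
        np.testing.assert_array_equal(model.predict(X), oracle.predict(X))

    def test_person_absent_from_window_still_fits(self, design):
        X, y, pids = design
        cfg = IdiographicConfig(forest_size=20, grid_search=False)
        model = mc.fit_idiographic(X, y, pids, "ghost", WeightScheme(1.0, 0.2), cfg, seed=7)
        assert np.isfinite(model.predict(X[:3])).all()

    def test_grid_search_selects_from_declared_grid(self, design):
        X, y, pids = design
        cfg = IdiographicConfig(forest_size=20, grid_search=True, cv_folds=3)
        model = mc.fit_idiographic(X, y, pids, "p1", WeightScheme(1.0, 0.2), cfg, seed=7)
        assert model.grid_searched
        assert model.max_features in per_split_candidate_grid(X.shape[1])
        assert model.split_rule in ("variance", "extratrees")


class TestGridHygiene:
    def test_candidate_grid_three_sorted_values_within_bounds(self):
        for p in (1, 2, 3, 10, 26):
            grid = per_split_candidate_grid(p)
            assert grid == sorted(grid)
            assert all(1 <= v <= p for v in grid)
            assert len(grid) == (3 if p >= 3 else p)

    def test_tuning_folds_are_subsets_of_training_rows(self):
        pids = np.array([f"p{i % 5}" for i in range(40)])
        folds = _cv_folds(pids, n_folds=3, seed=0)
        n = len(pids)
        for tr, va in folds:
            assert set(tr) <= set(range(n)) and set(va) <= set(range(n))
            assert len(set(tr) & set(va)) == 0

    def test_folds_blocked_by_person(self):
        pids = np.array([f"p{i % 5}" for i in range(40)])
        for tr, va in _cv_folds(pids, n_folds=3, seed=0):
            assert set(pids[tr]) & set(pids[va]) == set()


class TestPredictHour:
    def test_records_carry_both_prediction_columns(self, linear_df, codec):
        w = mc.build_window(linear_df, t=26, lookback=24)
        nomo = mc.fit_nomothetic(w, codec, NomotheticConfig(rounds=20), seed=0)
        Xtr = codec.transform(w.training)
        Xs = mc.augment_features(Xtr, nomo.predict(w.training))
        y = w.training["mood"].to_numpy()
        pids = w.training["person_id"].to_numpy()
        cfg = IdiographicConfig(forest_size=20, grid_search=False)
        models = {
            pid: mc.fit_idiographic(Xs, y, pids, pid, WeightScheme(1.0, 0.2), cfg, seed=1)
            for pid in ("pA", "pB")
        }
        recs = mc.predict_hour(models, nomo, w, imputation_id=0)
        assert set(recs.columns) >= {"yhat_nomothetic", "yhat_idiographic", "y_observed"}
        assert len(recs) == 2

    def test_person_without_outcome_at_t_gets_no_record(self, linear_df, codec):
        df = linear_df.copy()
        df.loc[(df["hour_index"] == 26) & (df["person_id"] == "pB"), "mood"] = np.nan
        w = mc.build_window(df, t=26, lookback=24)
        nomo = mc.fit_nomothetic(w, codec, NomotheticConfig(rounds=20), seed=0)
        Xtr = codec.transform(w.training)
        Xs = mc.augment_features(Xtr, nomo.predict(w.training))
        y = w.training["mood"].to_numpy()
        pids = w.training["person_id"].to_numpy()
        cfg = IdiographicConfig(forest_size=20, grid_search=False)
        models = {
            pid: mc.fit_idiographic(Xs, y, pids, pid, WeightScheme(1.0, 0.2), cfg, seed=1)
            for pid in ("pA", "pB")
        }
        recs = mc.predict_hour(models, nomo, w, imputation_id=0)
        assert set(recs["person_id"]) == {"pA"}
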