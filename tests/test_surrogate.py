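"""Surrogate dataset handling, metrics, grid search and training."""

import warnings

import numpy as np
import pandas as pd
import pytest

import fluorisk as fk
from fluorisk.errors import ConfigurationError, ExtrapolationWarning, UsageError
from fluorisk.surrogate import (
    CandidateResult,
    FeatureScaler,
    SurrogateConfig,
    SurrogateModel,
    _n_params,
    build_dataset,
    evaluate,
    grid_search,
    predict_hq,
    regression_metrics,
    standardize,
    train_final,
)

QUICK = SurrogateConfig(
    architectures=((32, 16),),
    l2=(0.01,),
    learning_rates=(0.01,),
    max_epochs=400,
    cv_max_epochs=150,
    patience=50,
    seed=0,
)


@pytest.fixture(scope="module")
def study():
    return fk.generate_study(seed=21)


@pytest.fixture(scope="module")
def dataset(study):
    return standardize(build_dataset(study, seed=21))


@pytest.fixture(scope="module")
def quick_model(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranked = grid_search(dataset, QUICK)
        return train_final(dataset, ranked[0], QUICK, seed=21)


class TestDataset:
    def test_default_split_is_69_8_8(self, dataset):
        assert dataset.n_rows("train") == 69
        assert dataset.n_rows("val") == 8
        assert dataset.n_rows("test") == 8

    def test_all_train_fractions(self, study):
        ds = build_dataset(study, fractions=(1.0, 0.0, 0.0), seed=1)
        assert ds.n_rows("train") == 85

    def test_bad_fractions_rejected(self, study):
        with pytest.raises(ConfigurationError):
            build_dataset(study, fractions=(0.8, 0.1, 0.2), seed=1)

    def test_reshuffling_preserves_row_multiset(self, study):
        a = build_dataset(study, seed=2)
        b = build_dataset(study, seed=2, fractions=(0.6, 0.2, 0.2))
        # same seed, different fractions: identical rows, different partition
        pd.testing.assert_frame_equal(a.features, b.features)
        assert not np.array_equal(a.split, b.split)

    def test_too_few_rows_rejected(self, study):
        with pytest.raises(UsageError):
            build_dataset(study[:2], seed=0)


class TestStandardize:
    def test_training_moments_after_transform(self, dataset):
        X, _ = dataset.rows("train")
        Z = dataset.scaler.transform(X)
        varying = ~dataset.scaler.constant
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0)[varying], 1, atol=1e-10)

    def test_constant_feature_centered_and_flagged(self, dataset):
        # EF is 365 days/year for every cohort
        i = list(dataset.scaler.names).index("EF")
        assert dataset.scaler.constant[i]
        assert dataset.scaler.scale[i] == 1.0

    def test_inverse_transform_roundtrip(self, dataset):
        X, _ = dataset.rows("test")
        np.testing.assert_allclose(
            dataset.scaler.inverse_transform(dataset.scaler.transform(X)), X
        )

    def test_scaler_uses_training_rows_only(self, study):
        ds = standardize(build_dataset(study, seed=3))
        all_rows = FeatureScaler.fit(
            ds.features.to_numpy(dtype=float), ds.features.columns
        )
        assert not np.allclose(all_rows.mean, ds.scaler.mean)


class TestMetrics:
    def test_hand_computed_toy_vectors(self):
        m = regression_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert m["R2"] == pytest.approx(0.5)
        assert m["RMSE"] == pytest.approx(0.5774, abs=1e-4)

    def test_perfect_and_mean_predictors(self):
        y = np.array([1.0, 2, 3, 4])
        perfect = regression_metrics(y, y)
        assert perfect["R2"] == 1.0 and perfect["RMSE"] == 0.0
        assert regression_metrics(y, np.full(4, y.mean()))["R2"] == pytest.approx(0.0)

    def test_agrees_with_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        yhat = y + rng.normal(scale=0.3, size=50)
        m = regression_metrics(y, yhat)
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert m["R2"] == pytest.approx(1 - ss_res / ss_tot)
        assert m["MSE"] == pytest.approx(ss_res / 50)


class TestGridSearch:
    def test_single_candidate_selected(self, dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = grid_search(dataset, QUICK)
        assert len(ranked) == 1
        assert ranked[0].architecture == (32, 16)
        assert np.isfinite(ranked[0].mean_cv_mse)

    def test_crushing_l2_ranks_below_moderate(self, dataset):
        config = SurrogateConfig(
            architectures=((32, 16),), l2=(0.01, 1000.0), learning_rates=(0.01,),
            cv_max_epochs=150, seed=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = grid_search(dataset, config)
        assert ranked[0].l2 == 0.01
        assert ranked[0].mean_cv_mse < ranked[-1].mean_cv_mse

    def test_parameter_count_formula(self):
        # 6 -> 4 -> 1: (6*4 + 4) + (4*1 + 1) = 33
        assert _n_params((4,)) == 33

    def test_infeasible_folds_rejected(self, study):
        tiny = build_dataset(study, seed=4)
        config = SurrogateConfig(k_folds=100, seed=0)
        with pytest.raises(UsageError):
            grid_search(standardize(tiny), config)


class TestTraining:
    def test_history_and_early_stopping_bookkeeping(self, quick_model):
        h = quick_model.history
        assert list(h.columns) == ["epoch", "train_mse", "val_mse"]
        assert len(h) <= QUICK.max_epochs
        assert quick_model.best_epoch <= len(h)
        # the running minimum of the training loss never increases
        running = h["train_mse"].cummin()
        assert (running.diff().dropna() <= 1e-15).all()

    def test_seeded_determinism(self, dataset):
        cand = CandidateResult((16,), 0.01, 0.01, 0.0, (), _n_params((16,)))
        cfg = SurrogateConfig(architectures=((16,),), max_epochs=100, patience=30, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = train_final(dataset, cand, cfg, seed=5)
            m2 = train_final(dataset, cand, cfg, seed=5)
        for w1, w2 in zip(m1.coefs, m2.coefs):
            np.testing.assert_array_equal(w1, w2)
        assert m1.metrics == m2.metrics

    def test_zero_target_learned_to_zero(self, study):
        ds = build_dataset(study, seed=6)
        ds = standardize(
            type(ds)(ds.features, np.zeros_like(ds.target), ds.split,
                     ds.cohort, ds.site_id, ds.seed)
        )
        cand = CandidateResult((16,), 0.01, 0.01, 0.0, (), _n_params((16,)))
        cfg = SurrogateConfig(architectures=((16,),), max_epochs=200, patience=30, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_final(ds, cand, cfg, seed=6)
        assert model.metrics["train"]["MSE"] < 1e-4

    def test_metrics_recomputable_from_stored_weights(self, quick_model, dataset):
        for split in ("train", "val", "test"):
            again = evaluate(quick_model, dataset, split)
            assert again == pytest.approx(dict(quick_model.metrics[split]))


class TestPrediction:
    def test_training_rows_predicted_within_rmse_scale(self, quick_model, dataset):
        X, y = dataset.rows("train")
        yhat = predict_hq(quick_model, X, warn=False)
        rmse = quick_model.metrics["train"]["RMSE"]
        assert np.abs(yhat - y).mean() <= max(5 * rmse, 0.05)

    def test_doubling_concentration_increases_prediction(self, quick_model):
        children = fk.DEFAULT_COHORTS[0]
        base = {"C": 1.2, "EF": 365, "IR": children.IR, "ED": children.ED,
                "BW": children.BW, "AT": children.AT}
        lo = predict_hq(quick_model, base, warn=False)[0]
        hi = predict_hq(quick_model, {**base, "C": 2.4}, warn=False)[0]
        assert hi > lo

    def test_out_of_hull_input_warns_but_returns(self, quick_model):
        children = fk.DEFAULT_COHORTS[0]
        far = {"C": 50.0, "EF": 365, "IR": children.IR, "ED": children.ED,
               "BW": children.BW, "AT": children.AT}
        with pytest.warns(ExtrapolationWarning):
            value = predict_hq(quick_model, far)
        assert np.isfinite(value).all()

    def test_json_roundtrip_preserves_predictions(self, quick_model, dataset):
        restored = SurrogateModel.from_json(quick_model.to_json())
        X, _ = dataset.rows("test")
        np.testing.assert_allclose(
            predict_hq(restored, X, warn=False),
            predict_hq(quick_model, X, warn=False),
        )
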