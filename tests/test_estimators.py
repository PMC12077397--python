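"""Model contract: tuned fitting, nested out-of-fold prediction, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import (
    accuracy_score,
    explained_variance_score,
    mean_absolute_error,
)

import prosplit as ps
from prosplit._seeds import spawn_seeds
from prosplit.models import (
    _fit_linear,
    _fit_logistic,
    _fit_ridge,
    _labels_from_linear,
    _predict_raw,
    _standardize_params,
    make_folds,
)


class TestFitTuned:
    def test_separable_toy_reaches_perfect_training_accuracy(self, toy_separable, clf_spec):
        model = ps.fit_tuned(toy_separable, clf_spec, seed=0)
        pred = ps.predict(model, toy_separable.features)
        assert ps.score(toy_separable.target, pred, "accuracy") == 1.0

    def test_deterministic_given_seed(self, strong_regression, reg_spec):
        a = ps.fit_tuned(strong_regression, reg_spec, seed=5)
        b = ps.fit_tuned(strong_regression, reg_spec, seed=5)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.intercept == b.intercept
        assert a.chosen_regularization == b.chosen_regularization

    def test_chosen_regularization_matches_brute_force_grid_loop(self):
        """Tuning oracle: exhaustive loop over the grid with identical folds."""
        base = ps.make_regression(
            ps.GeneratorConfig(n=60, p=10, task="regression", target_signal=0.5, seed=7)
        )
        # make two columns nearly collinear
        X = base.features.copy()
        X[:, 9] = 0.95 * X[:, 0] + 0.05 * X[:, 9]
        ds = ps.Dataset(X, base.target, "regression")
        spec = ps.ModelSpec("regression")
        model = ps.fit_tuned(ds, spec, seed=7)

        folds = make_folds(ds, spec, seed=7)
        best_reg, best_score = None, -np.inf
        for reg in sorted(spec.regularization_grid):
            fold_scores = []
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(ds.n), test_idx)
                center, scale = _standardize_params(ds.features[train_idx])
                coef, b = _fit_linear(
                    (ds.features[train_idx] - center) / scale,
                    ds.target[train_idx],
                    "regression",
                    reg,
                )
                pred = _predict_raw(ds.features[test_idx], coef, b, center, scale)
                fold_scores.append(ps.score(ds.target[test_idx], pred, spec.scorer))
            if np.mean(fold_scores) >= best_score:
                best_score, best_reg = np.mean(fold_scores), reg
        assert model.chosen_regularization == best_reg

    def test_single_class_input_rejected(self, clf_spec):
        with pytest.raises(ValueError, match="degenerate target"):
            ps.Dataset(np.ones((6, 2)), np.zeros(6), "classification")

    def test_too_small_sample_rejected(self, reg_spec):
        tiny = ps.Dataset(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]), "regression")
        with pytest.raises(ValueError, match="insufficient sample"):
            ps.fit_tuned(tiny, reg_spec, seed=0)


class TestSolvers:
    """The internal ridge / logistic solvers must match scikit-learn."""

    @pytest.mark.parametrize("reg", [0.1, 1.0, 10.0])
    def test_ridge_matches_sklearn(self, reg):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 8))
        y = X[:, 0] + rng.normal(size=50)
        coef, intercept = _fit_ridge(X, y, reg)
        sk = Ridge(alpha=reg).fit(X, y)
        np.testing.assert_allclose(coef, sk.coef_, atol=1e-8)
        assert abs(intercept - sk.intercept_) < 1e-8

    @pytest.mark.parametrize("reg", [0.1, 1.0, 10.0])
    def test_logistic_matches_sklearn(self, reg):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        coef, intercept = _fit_logistic(Xs, y, reg)
        sk = LogisticRegression(
            C=1.0 / reg, solver="newton-cholesky", tol=1e-10, max_iter=1000
        ).fit(Xs, y)
        np.testing.assert_allclose(coef, sk.coef_[0], atol=1e-5)
        assert abs(intercept - sk.intercept_[0]) < 1e-5


class TestPredict:
    def test_zero_coefficients_predict_zero(self):
        model = ps.FittedModel(
            coefficients=np.zeros(3), intercept=0.0, chosen_regularization=1.0,
            center=np.zeros(3), scale=np.ones(3), task="regression", n_train=10,
        )
        assert np.all(ps.predict(model, np.random.default_rng(0).normal(size=(5, 3))) == 0)

    def test_toy_model_reproduces_training_labels(self, toy_separable, clf_spec):
        model = ps.fit_tuned(toy_separable, clf_spec, seed=0)
        np.testing.assert_array_equal(
            ps.predict(model, toy_separable.features), [0, 0, 1, 1]
        )

    def test_feature_mismatch_rejected(self, toy_separable, clf_spec):
        model = ps.fit_tuned(toy_separable, clf_spec, seed=0)
        with pytest.raises(ValueError, match="feature mismatch"):
            ps.predict(model, np.ones((2, 3)))

    def test_predictions_invariant_to_consistent_feature_rescaling(self, reg_spec):
        ds = ps.make_regression(
            ps.GeneratorConfig(n=80, p=4, task="regression", target_signal=0.6, seed=2)
        )
        scales = np.array([100.0, 0.01, 3.0, 1.0])
        rescaled = ps.Dataset(ds.features * scales, ds.target, "regression")
        m1 = ps.fit_tuned(ds, reg_spec, seed=4)
        m2 = ps.fit_tuned(rescaled, reg_spec, seed=4)
        Xnew = np.random.default_rng(9).normal(size=(10, 4))
        np.testing.assert_allclose(
            ps.predict(m1, Xnew), ps.predict(m2, Xnew * scales), rtol=1e-8
        )


class TestCvPredict:
    def test_folds_partition_indices(self, strong_regression, reg_spec, clf_spec,
                                     noise_classification):
        for ds, spec in [(strong_regression, reg_spec), (noise_classification, clf_spec)]:
            folds = make_folds(ds, spec, seed=1)
            joined = np.concatenate(folds)
            assert len(joined) == ds.n
            assert len(np.unique(joined)) == ds.n

    def test_out_of_fold_no_worse_than_in_sample_on_average(self, reg_spec):
        diffs = []
        for s in range(20):
            ds = ps.make_regression(
                ps.GeneratorConfig(n=20, p=3, task="regression", target_signal=0.7, seed=s)
            )
            oof = ps.cv_predict(ds, reg_spec, seed=s).score()
            model = ps.fit_tuned(ds, reg_spec, seed=s)
            insample = ps.score(
                ds.target, ps.predict(model, ds.features), reg_spec.scorer
            )
            diffs.append(insample - oof)
        assert np.mean(diffs) >= 0

    def test_null_classification_accuracy_near_chance(self, clf_spec):
        """Out-of-fold accuracy on pure-noise balanced data stays inside the
        99% binomial band around 0.5 (mean over 50 seeded datasets)."""
        accs = []
        for s in range(50):
            ds = ps.make_classification(
                ps.GeneratorConfig(
                    n=100, p=5, task="classification", target_signal=0.0, seed=1000 + s
                )
            )
            accs.append(ps.cv_predict(ds, clf_spec, seed=s).score())
        half_width = 2.576 * np.sqrt(0.25 / (50 * 100))
        # nested CV under the null is slightly pessimistic; allow the band
        # to extend downward by the known anti-learning bias scale 1/n
        assert 0.5 - half_width - 0.02 <= np.mean(accs) <= 0.5 + half_width

    def test_fold_predictions_match_manual_refit(self, reg_spec):
        """No-leakage contract: each fold's predictions come from a model
        (and preprocessing) fit on that fold's complement only."""
        ds = ps.make_regression(
            ps.GeneratorConfig(n=40, p=3, task="regression", target_signal=0.5, seed=6)
        )
        seed = 11
        sample = ps.cv_predict(ds, reg_spec, seed=seed)
        outer_seed, *inner_seeds = spawn_seeds(seed, 1 + reg_spec.cv_folds)
        folds = make_folds(ds, reg_spec, outer_seed)
        for i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(ds.n), test_idx)
            model = ps.fit_tuned(ds.subset(train_idx), reg_spec, inner_seeds[i])
            np.testing.assert_allclose(
                sample.prediction[test_idx],
                ps.predict(model, ds.features[test_idx]),
            )

    def test_per_fold_standardization_constants_differ(self, reg_spec):
        # one extreme row shifts the center of every fold that trains on it
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        X[0] += 50.0
        ds = ps.Dataset(X, rng.normal(size=30), "regression")
        folds = make_folds(ds, reg_spec, seed=0)
        centers = []
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(ds.n), test_idx)
            centers.append(_standardize_params(ds.features[train_idx])[0])
        assert len({tuple(np.round(c, 6)) for c in centers}) == len(folds)


class TestScore:
    def test_known_values(self):
        assert ps.score([0, 1, 1], [0, 1, 1], "accuracy") == 1.0
        assert ps.score([0.0, 2.0], [1.0, 3.0], "neg_mean_absolute_error") == -1.0
        truth = np.array([1.0, 2.0, 4.0])
        assert ps.score(truth, truth, "explained_variance") == 1.0

    def test_matches_sklearn_metrics(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(size=40)
        pred = truth + rng.normal(scale=0.5, size=40)
        assert ps.score(truth, pred, "neg_mean_absolute_error") == pytest.approx(
            -mean_absolute_error(truth, pred)
        )
        assert ps.score(truth, pred, "explained_variance") == pytest.approx(
            explained_variance_score(truth, pred)
        )
        labels = (truth > 0).astype(float)
        plabels = (pred > 0).astype(float)
        assert ps.score(labels, plabels, "accuracy") == pytest.approx(
            accuracy_score(labels, plabels)
        )

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="empty score input"):
            ps.score([], [], "accuracy")
        with pytest.raises(ValueError, match="zero-variance target"):
            ps.score([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "explained_variance")

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_score_bounds(self, truth, seed):
        rng = np.random.default_rng(seed)
        truth = np.asarray(truth)
        pred = rng.normal(size=len(truth))
        assert ps.score(truth, pred, "neg_mean_absolute_error") <= 0
        labels = (truth > 0).astype(float)
        assert 0 <= ps.score(labels, (pred > 0).astype(float), "accuracy") <= 1
        if np.var(truth) > 0:
            assert ps.score(truth, pred, "explained_variance") <= 1

    def test_scorer_task_compatibility_enforced(self):
        with pytest.raises(ValueError, match="incompatible"):
            ps.ModelSpec("classification", scorer_id="explained_variance")

    def test_chance_levels(self, noise_classification, strong_regression):
        assert ps.SCORERS["accuracy"].chance_level(noise_classification) == pytest.approx(
            0.5, abs=0.01
        )
        assert ps.SCORERS["explained_variance"].chance_level(strong_regression) == 0.0

    def test_labels_from_linear_threshold_zero(self):
        classes = np.array([0.0, 1.0])
        np.testing.assert_array_equal(
            _labels_from_linear(np.array([-0.1, 0.0, 0.1]), classes), [0, 0, 1]
        )
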