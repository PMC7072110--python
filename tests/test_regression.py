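"""Age scaling, SVR/KRR fits, cross-validation, ensembles and stratification."""

import numpy as np
import pytest

from boneal import phantoms as ph
from boneal.metrics import mae
from boneal.regression import (
    ContractError,
    EnsembleConfig,
    RegressorConfig,
    balance_by_age,
    cross_validate,
    fit_ensemble,
    fit_regressor,
    scale_age,
    stratified_fit,
    unscale_age,
)


def _closed_form_krr(Xtr, ytr, Xte, alpha):
    """Independent oracle: z-score features, center targets, dual ridge."""
    mu, sd = Xtr.mean(0), Xtr.std(0)
    sd = np.where(sd == 0, 1.0, sd)
    Ztr, Zte = (Xtr - mu) / sd, (Xte - mu) / sd
    K = Ztr @ Ztr.T
    yc = ytr - ytr.mean()
    return ytr.mean() + Zte @ Ztr.T @ np.linalg.solve(K + alpha * np.eye(len(ytr)), yc)


class TestScaling:
    def test_endpoints_and_midpoint(self):
        assert scale_age(0) == 0.0
        assert scale_age(228) == 1.0
        assert scale_age(114) == 0.5

    def test_roundtrip_all_integer_months(self):
        months = np.arange(0, 229)
        assert np.allclose(unscale_age(scale_age(months)), months)

    def test_negative_age_rejected(self):
        with pytest.raises(ContractError):
            scale_age(-1)

    def test_out_of_range_prediction_clipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert unscale_age(1.2) == 228.0
        assert "clipping" in caplog.text


class TestKRR:
    def test_predictions_match_closed_form_on_random_problems(self, rng):
        for _ in range(20):
            X = rng.standard_normal((10, 3))
            y = rng.random(10)
            fitted = fit_regressor(X, y, RegressorConfig(family="krr"))
            expected = _closed_form_krr(X, y, X, alpha=1.0)
            assert np.allclose(fitted.predict(X), expected, atol=1e-6)

    def test_recovers_exact_linear_map_with_tiny_regularization(self, rng):
        w = np.array([0.3, -0.2, 0.1])
        X = rng.standard_normal((40, 3))
        y = X @ w / 4 + 0.5
        fitted = fit_regressor(X, y, RegressorConfig(family="krr", krr_regularization=1e-8))
        assert np.allclose(fitted.predict(X), y, atol=1e-4)

    def test_constant_target_predicted_everywhere(self, rng):
        X = rng.standard_normal((15, 1))
        fitted = fit_regressor(X, np.full(15, 0.37), RegressorConfig(family="krr"))
        assert np.allclose(fitted.predict(X), 0.37, atol=1e-8)

    def test_zero_variance_features_warn_but_fit(self, rng):
        X = np.ones((10, 2))
        with pytest.warns(UserWarning, match="zero variance"):
            fit_regressor(X, rng.random(10), RegressorConfig(family="krr"))

    def test_svr_fits_linear_data(self, rng):
        X = rng.standard_normal((60, 2))
        y = np.clip(0.5 + 0.1 * X[:, 0], 0, 1)
        fitted = fit_regressor(X, y, RegressorConfig(family="svr"))
        assert mae(y, fitted.predict(X)) < 0.05


class TestCrossValidation:
    def test_folds_partition_the_data(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.uniform(0, 228, 40)
        rep = cross_validate(X, y, folds=5, seed=0)
        counts = np.bincount(rep.fold_assignment, minlength=5)
        assert counts.sum() == 40 and counts.min() >= 1

    def test_same_seed_same_assignment(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.uniform(0, 228, 30)
        a = cross_validate(X, y, folds=5, seed=4)
        b = cross_validate(X, y, folds=5, seed=4)
        assert a.fold_assignment == b.fold_assignment
        assert np.array_equal(a.predictions_months, b.predictions_months)

    def test_pooled_mae_recomputable_from_stored_predictions(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.uniform(0, 228, 30)
        rep = cross_validate(X, y, folds=5, seed=1)
        assert rep.pooled.mae == pytest.approx(mae(y, rep.predictions_months))

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(Exception):
            cross_validate(rng.random((3, 2)), np.array([1.0, 2.0, 3.0]), folds=5)


class TestEnsembles:
    def test_single_member_without_resampling_equals_base_fit(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.random(20)
        single = fit_regressor(X, y, RegressorConfig(family="krr"))
        bag = fit_ensemble(X, y, EnsembleConfig(method="bagging", n_estimators=1, bootstrap=False))
        assert np.allclose(bag.predict(X), single.predict(X), atol=1e-10)

    def test_bagging_prediction_is_mean_of_members(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.random(25)
        bag = fit_ensemble(X, y, EnsembleConfig(method="bagging", n_estimators=7, seed=1))
        member_preds = np.stack([est.predict(X) for est in bag.estimator.estimators_])
        assert np.allclose(bag.predict(X), member_preds.mean(axis=0), atol=1e-10)

    def test_monte_carlo_variance_shrinks_with_more_members(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.clip(0.5 + 0.2 * X[:, 0] + rng.normal(0, 0.05, 60), 0, 1)
        probe = rng.standard_normal((1, 3))
        spread = {}
        for n in (1, 5, 21):
            preds = [
                fit_ensemble(X, y, EnsembleConfig(method="bagging", n_estimators=n, seed=s)).predict(probe)[0]
                for s in range(6)
            ]
            spread[n] = np.std(preds)
        assert spread[21] <= spread[1] + 1e-6
        assert spread[5] <= spread[1] * 1.5  # noisy but should not blow up

    def test_adaboost_runs_and_predicts_in_range(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.clip(0.5 + 0.1 * X[:, 0], 0, 1)
        ada = fit_ensemble(X, y, EnsembleConfig(method="adaboost", n_estimators=5, seed=0))
        assert mae(y, ada.predict(X)) < 0.1

    def test_invalid_count_rejected(self):
        with pytest.raises(Exception):
            EnsembleConfig(n_estimators=0)


class TestStratified:
    def _sex_dependent_data(self, seed, n=150):
        # maturity -> age slope differs by sex, so per-sex fits should win
        g = np.random.default_rng(seed)
        m = g.uniform(0, 1, n)
        male = g.random(n) < 0.5
        X = np.column_stack([m, m * 0.5 + g.normal(0, 0.01, n)])
        age = np.where(male, 210 * m + 10, 228 * m)
        age = np.clip(age + g.normal(0, 5, n), 0, 228)
        return X, age, male

    def test_cohort_sizes_sum_to_n(self):
        X, age, male = self._sex_dependent_data(0)
        out = stratified_fit(X, age, male, RegressorConfig(family="krr"), folds=5, seed=0)
        assert out["male"][1].pooled.n + out["female"][1].pooled.n == out["all"][1].pooled.n

    def test_male_report_uses_only_male_rows(self):
        X, age, male = self._sex_dependent_data(1)
        out = stratified_fit(X, age, male, RegressorConfig(family="krr"), folds=5, seed=0)
        assert out["male"][1].pooled.n == int(male.sum())

    def test_per_sex_fits_beat_mixed_fit_on_sex_dependent_data(self):
        diffs = []
        for seed in (0, 1, 2):
            X, age, male = self._sex_dependent_data(seed)
            out = stratified_fit(X, age, male, RegressorConfig(family="krr"), folds=5, seed=seed)
            per_sex = (
                out["male"][1].pooled.mae * male.sum() + out["female"][1].pooled.mae * (~male).sum()
            ) / len(age)
            diffs.append(per_sex - out["all"][1].pooled.mae)
        assert np.mean(diffs) <= 0.5  # months; per-sex at least matches mixed

    def test_empty_cohort_skipped_with_warning(self, rng):
        X = rng.standard_normal((20, 2))
        age = rng.uniform(0, 228, 20)
        with pytest.warns(UserWarning, match="female"):
            out = stratified_fit(X, age, np.ones(20, dtype=bool), folds=5)
        assert "female" not in out and "male" in out


def test_balance_by_age_equalizes_bins(rng):
    ages = np.concatenate([rng.uniform(0, 12, 50), rng.uniform(216, 228, 10)])
    keep = balance_by_age(ages, seed=0)
    bins = (ages[keep] // 12).astype(int)
    _, counts = np.unique(bins, return_counts=True)
    assert len(set(counts)) == 1


def test_parameter_recovery_window_on_geometry_features():
    """Jitter-free geometry + 6-month age noise: KRR neither under- nor overfits."""
    cfg = ph.VariationConfig(geometry_jitter=0.0)
    g = np.random.default_rng(3)
    params = [ph.sample_phantom_params(g, cfg) for _ in range(500)]
    X = np.stack([ph.geometry_features(p) for p in params])
    ages = np.clip(np.array([228 * p.maturity for p in params]) + g.normal(0, 6, 500), 0, 228)
    rep = cross_validate(X, ages, RegressorConfig(family="krr"), folds=5, seed=0)
    assert 3.0 <= rep.pooled.mae <= 9.0
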