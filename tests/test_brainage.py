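import numpy as np
import pytest
from scipy import stats

from pbsikit.brainage import (
    DEFAULT_C_GRID,
    BrainAgeConfig,
    BrainAgeResult,
    ModelPerformance,
    RVRegressor,
    compare_models_mae,
    compare_ded_prd_cognition,
    cross_validated_brainage,
    fit_gpr_linear,
    fit_rvr,
    fit_svr_linear,
    site_residualized_age,
    split_ded_prd,
    stratified_age_folds,
)


def _linear_age_features(rng, n=300, r2=0.8, n_feat=20):
    """Features carrying age through a shared noisy proxy: the best possible
    predictor recovers age + eta, so the irreducible MAE is sd(eta)*sqrt(2/pi)."""
    age = rng.uniform(6, 20, n)
    sigma = np.sqrt(np.var(age) * (1 - r2) / r2)
    eta = rng.normal(0, sigma, n)
    w = rng.normal(1.0, 0.3, n_feat)
    X = np.outer(age + eta, w) + rng.normal(0, 0.5, (n, n_feat))
    return X, age, sigma


class TestCGrid:
    def test_grid_endpoints(self):
        assert len(DEFAULT_C_GRID) == 9
        assert DEFAULT_C_GRID[0] == pytest.approx(0.0078125)
        assert DEFAULT_C_GRID[-1] == pytest.approx(128.0)


class TestSVR:
    def test_linear_recovery(self, rng):
        x = rng.uniform(6, 20, 120)
        X = x[:, None]
        model, C = fit_svr_linear(X[:80], x[:80], seed=0)
        assert np.abs(model.predict(X[80:]) - x[80:]).mean() < 0.12

    def test_constant_target(self, rng):
        X = rng.normal(size=(30, 3))
        model, _ = fit_svr_linear(X, np.full(30, 12.0))
        assert np.allclose(model.predict(X), 12.0, atol=0.2)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="samples"):
            fit_svr_linear(rng.normal(size=(1, 2)), np.array([1.0]))


class TestRVR:
    def test_noiseless_linear(self, rng):
        X = rng.normal(size=(50, 5))
        y = 2.0 * X[:, 0]
        model, weights = fit_rvr(X, y)
        Xte = rng.normal(size=(30, 5))
        assert np.abs(model.predict(Xte) - 2.0 * Xte[:, 0]).max() < 1e-3

    def test_pure_noise_prunes_most_bases(self, rng):
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        model = RVRegressor().fit(X, y)
        assert model.n_relevance_vectors <= 0.2 * 60

    def test_single_point_degenerate(self, rng):
        with pytest.warns(UserWarning, match="single training point"):
            model = RVRegressor().fit(np.array([[1.0, 2.0]]), np.array([7.0]))
        assert np.allclose(model.predict(rng.normal(size=(5, 2))), 7.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            RVRegressor().fit(np.array([[1.0], [np.inf]]), np.array([1.0, 2.0]))


class TestGPR:
    def test_noiseless_linear(self, rng):
        x = rng.uniform(6, 20, 80)
        model, info = fit_gpr_linear(x[:60, None], x[:60])
        assert np.abs(model.predict(x[60:, None]) - x[60:]).mean() < 0.05

    def test_pure_noise_predicts_mean(self, rng):
        y = rng.normal(10.0, 1.0, 100)
        X = rng.normal(size=(100, 5))
        model, _ = fit_gpr_linear(X, y)
        pred = model.predict(rng.normal(size=(50, 5)))
        assert np.all(np.abs(pred - y.mean()) < 0.2 * y.std())

    def test_duplicate_rows_ok(self, rng):
        X = np.repeat(rng.normal(size=(10, 3)), 2, axis=0)
        y = np.repeat(rng.normal(size=10), 2)
        model, _ = fit_gpr_linear(X, y)
        assert np.isfinite(model.predict(X)).all()


class TestStratifiedFolds:
    def test_partition(self, rng):
        age = rng.uniform(6, 20, 103)
        folds = stratified_age_folds(age, 10, rng)
        assert folds.size == 103
        counts = np.bincount(folds, minlength=10)
        assert counts.min() >= 10 and counts.max() <= 11

    def test_age_balance(self, rng):
        age = rng.uniform(6, 20, 200)
        folds = stratified_age_folds(age, 10, rng)
        fold_means = [age[folds == k].mean() for k in range(10)]
        assert np.ptp(fold_means) < 1.5


class TestCrossValidatedBrainAge:
    def test_known_signal_recovery(self, rng):
        X, age, sigma = _linear_age_features(rng)
        cfg = BrainAgeConfig(model="rvr", n_shuffles=3, seed=1)
        perf, nc_res, _ = cross_validated_brainage(X, age, cfg)
        assert perf.rho.mean() >= 0.85
        floor = sigma * np.sqrt(2 / np.pi)
        assert abs(perf.mae.mean() - floor) <= 0.25 * floor
        assert np.all(perf.mae <= perf.rmse)

    def test_each_subject_held_out_once_per_shuffle(self, rng):
        X, age, _ = _linear_age_features(rng, n=80)
        cfg = BrainAgeConfig(model="rvr", n_folds=5, n_shuffles=2, seed=3)
        perf, _, _ = cross_validated_brainage(X, age, cfg)
        for folds in perf.fold_assignments:
            assert folds.size == 80
            assert set(folds) == set(range(5))

    def test_determinism(self, rng):
        X, age, _ = _linear_age_features(rng, n=60)
        cfg = BrainAgeConfig(model="rvr", n_folds=4, n_shuffles=2, seed=5)
        _, a, _ = cross_validated_brainage(X, age, cfg)
        _, b, _ = cross_validated_brainage(X, age, cfg)
        assert np.array_equal(a.brain_age, b.brain_age)

    def test_asd_predictions_returned(self, rng):
        X, age, _ = _linear_age_features(rng, n=60)
        Xa, aa, _ = _linear_age_features(rng, n=30)
        cfg = BrainAgeConfig(model="rvr", n_folds=4, n_shuffles=2, seed=5)
        _, _, asd = cross_validated_brainage(X, age, cfg, asd_X=Xa, asd_age=aa)
        assert asd.brain_age.shape == (30,)
        assert np.allclose(asd.gap, asd.brain_age - aa)

    def test_shuffle_averaging_reduces_variance(self, rng):
        X, age, _ = _linear_age_features(rng, n=100)

        def preds(n_shuffles, seed):
            cfg = BrainAgeConfig(model="rvr", n_folds=5,
                                 n_shuffles=n_shuffles, seed=seed)
            return cross_validated_brainage(X, age, cfg)[1].brain_age

        single = np.var([preds(1, s) for s in range(6)], axis=0).mean()
        averaged = np.var([preds(4, 100 + s) for s in range(6)], axis=0).mean()
        assert averaged < single


class TestCompareModels:
    def _perf(self, mae, name="m"):
        mae = np.asarray(mae, dtype=float)
        return ModelPerformance(model=name, rho=np.zeros_like(mae),
                                mae=mae, rmse=mae + 1)

    def test_identical_mae(self):
        a = self._perf([1.0, 2, 3], "a")
        b = self._perf([1.0, 2, 3], "b")
        c = self._perf([1.0, 2, 4], "c")
        df = compare_models_mae(a, b, c)
        row = df[(df.model_a == "a") & (df.model_b == "b")].iloc[0]
        assert row.t == 0.0 and row.p == 1.0

    def test_constant_offset_degenerate(self):
        a = self._perf([1.0, 2, 3], "a")
        b = self._perf([2.0, 3, 4], "b")
        df = compare_models_mae(a, b)
        assert df.iloc[0].p == 0.0

    def test_threshold(self):
        perfs = [self._perf(np.arange(10) + i, f"m{i}") for i in range(3)]
        df = compare_models_mae(*perfs)
        assert df.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 3)

    def test_null_calibration(self, rng):
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            a = self._perf(rng.normal(2, 0.3, 10), "a")
            b = self._perf(rng.normal(2, 0.3, 10), "b")
            hits += compare_models_mae(a, b).iloc[0].p < 0.05 / 3
        assert 0.005 <= hits / n_sims <= 0.035

    def test_mismatched_shuffles(self):
        with pytest.raises(ValueError, match="shuffle"):
            compare_models_mae(self._perf([1, 2]), self._perf([1, 2, 3]))


class TestSplitDedPrd:
    def _result(self, brain_age, age):
        return BrainAgeResult(brain_age=np.asarray(brain_age, float),
                              age=np.asarray(age, float))

    def test_rule_examples(self):
        # SD of brain_age (12, 14, 10, ...) engineered to 2.0 via fixture below
        brain_age = np.array([10.0, 15.0, 12.5, 11.0, 13.26])
        age = np.array([12.0, 12.0, 12.0, 12.0, 12.0])
        sd = np.std(brain_age, ddof=1)
        split = split_ded_prd(self._result(brain_age, age))
        want = []
        for ba in brain_age:
            if ba + 0.5 * sd < 12.0:
                want.append("DED")
            elif ba - 0.5 * sd > 12.0:
                want.append("PRD")
            else:
                want.append("neither")
        assert list(split.dev_label) == want

    def test_three_way_partition(self, rng):
        ba = rng.normal(12, 3, 200)
        age = rng.uniform(6, 20, 200)
        split = split_ded_prd(self._result(ba, age))
        lab = split.dev_label
        assert np.all(np.isin(lab, ["DED", "PRD", "neither"]))
        sd = np.std(ba, ddof=1)
        assert np.array_equal(lab == "DED", ba + 0.5 * sd < age)
        assert np.array_equal(lab == "PRD", ba - 0.5 * sd > age)

    def test_zero_sd_all_neither(self):
        with pytest.warns(UserWarning, match="zero SD"):
            split = split_ded_prd(self._result([10.0, 10.0], [8.0, 14.0]))
        assert list(split.dev_label) == ["neither", "neither"]


class TestCognitionComparison:
    def test_planted_ver_difference_detected(self, rng):
        import pandas as pd

        n = 200
        ba = np.concatenate([rng.normal(8, 1, 100), rng.normal(16, 1, 100)])
        age = np.full(n, 12.0) + rng.normal(0, 0.5, n)
        split = split_ded_prd(BrainAgeResult(brain_age=ba, age=age))
        assert np.sum(split.dev_label == "DED") > 0
        assert np.sum(split.dev_label == "PRD") > 0
        ver = rng.normal(20, 5, n)
        ver[split.dev_label == "PRD"] += 5.0
        pheno = pd.DataFrame({
            "age": age, "sex": rng.integers(0, 2, n),
            "fiq": rng.normal(100, 15, n), "adi_rrb": rng.normal(20, 5, n),
            "adi_soc": rng.normal(20, 5, n), "adi_ver": ver})
        out = compare_ded_prd_cognition(split, pheno)
        assert out["adi_ver"].p_value < 0.01
        assert out["fiq"].p_value > 0.01


class TestSiteResidualizedAge:
    def test_shifted_site_corrected(self, rng):
        age = np.concatenate([rng.uniform(8, 12, 100), rng.uniform(8, 12, 100) + 3])
        sites = np.array([0] * 100 + [1] * 100)
        adj = site_residualized_age(age, sites)
        shift = age[100:].mean() - adj[100:].mean()
        assert shift == pytest.approx(1.5, abs=0.3)  # half the 3y gap (grand mean kept)
        assert adj[:100].mean() == pytest.approx(adj[100:].mean())

    def test_balanced_sites_nearly_identity(self, rng):
        age = rng.uniform(6, 20, 400)
        sites = np.tile([0, 1], 200)
        adj = site_residualized_age(age, sites)
        assert np.abs(adj - age).max() < 1.0

    def test_single_site_warns_identity(self, rng):
        age = rng.uniform(6, 20, 30)
        with pytest.warns(UserWarning, match="single site"):
            adj = site_residualized_age(age, np.zeros(30))
        assert np.array_equal(adj, age)

    def test_constant_age(self):
        age = np.full(20, 10.0)
        adj = site_residualized_age(age, np.tile([0, 1], 10))
        assert np.allclose(adj, 10.0)
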