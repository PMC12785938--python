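import numpy as np
import pytest

from incepspect.evaluate import (
    EvalReport,
    ExperimentConfig,
    r2,
    residual_table,
    rmse,
    rmsecv,
    rpd,
    rpd_label,
    run_experiment,
)
from incepspect.nets import InceptionSpec, NetConfig

from conftest import make_set


class TestR2:
    def test_perfect(self):
        assert r2([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]) == 1.0

    def test_mean_predictor_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r2(y, np.full(3, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_half(self):
        assert r2([0.0, 1.0, 2.0], [0.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_constant_reference_errors(self):
        with pytest.raises(ValueError, match="constant"):
            r2([1.0, 1.0], [0.5, 1.5])

    def test_order_invariance(self, rng):
        y = rng.uniform(size=30)
        p = y + rng.normal(scale=0.1, size=30)
        perm = rng.permutation(30)
        assert r2(y, p) == pytest.approx(r2(y[perm], p[perm]), abs=1e-12)


class TestRmse:
    def test_equal_vectors_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_known_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_single_pair(self):
        assert rmse([1.0], [0.0]) == 1.0

    def test_order_invariance(self, rng):
        y = rng.uniform(size=25)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert rmse(y, p) == pytest.approx(rmse(y[perm], p[perm]), abs=1e-12)


class TestRpd:
    def test_identity_with_sd(self, rng):
        for _ in range(10):
            y = rng.uniform(size=20)
            p = y + rng.normal(scale=0.1, size=20)
            e = rmse(y, p)
            assert rpd(y, p) * e == pytest.approx(y.std(ddof=1), abs=1e-10)

    def test_unit_rpd_is_poor(self, rng):
        y = rng.uniform(size=50)
        # shift predictions so rmse equals sd(y)
        p = y + y.std(ddof=1)
        assert rpd(y, p) == pytest.approx(1.0, rel=1e-6)
        assert rpd_label(rpd(y, p)) == "poor"

    def test_bands(self):
        assert rpd_label(2.39) == "poor"
        assert rpd_label(2.4) == "acceptable"
        assert rpd_label(2.7) == "acceptable"
        assert rpd_label(2.999) == "acceptable"
        assert rpd_label(3.0) == "excellent"
        assert rpd_label(6.2) == "excellent"

    def test_zero_rmse_infinite(self):
        assert rpd([0.0, 1.0], [0.0, 1.0]) == np.inf


class TestRmsecv:
    def test_noiseless_linear_plsr_tiny(self, rng):
        n, p = 30, 8
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta
        y = (y - y.min()) / (y.max() - y.min())
        data = make_set(X, y)
        assert rmsecv("plsr", data, "raw", folds=5, seed=0) < 1e-6

    def test_same_seed_same_value(self, tiny_dataset):
        a = rmsecv("plsr", tiny_dataset, "raw", folds=5, seed=4)
        b = rmsecv("plsr", tiny_dataset, "raw", folds=5, seed=4)
        assert a == b

    def test_strategy_refits_selection_per_fold(self, tiny_dataset):
        """msc+cars path runs end to end with per-fold refits and stays
        reproducible."""
        kwargs = {"cars": {"mc_runs": 5, "folds": 3}}
        a = rmsecv("plsr", tiny_dataset, "msc+cars", folds=3, seed=2,
                   selector_kwargs=kwargs)
        b = rmsecv("plsr", tiny_dataset, "msc+cars", folds=3, seed=2,
                   selector_kwargs=kwargs)
        assert a == b
        assert a >= 0

    def test_net_model_spec(self, tiny_dataset):
        cfg = NetConfig(stem_filters=2, inception1=InceptionSpec(1, 1, 1, 1),
                        inception2=InceptionSpec(1, 1, 1, 1), fc_units=4,
                        max_epochs=2, patience=2)
        val = rmsecv("incepspect_cbam", tiny_dataset, "raw", folds=3, seed=0,
                     net_config=cfg)
        assert np.isfinite(val) and val >= 0

    def test_mean_predictor_close_to_sd(self, rng):
        """Fold-wise mean predictor gives RMSECV ~ sd(y)."""
        from sklearn.model_selection import KFold

        y = rng.uniform(size=100)
        kf = KFold(n_splits=5, shuffle=True, random_state=0)
        resid = np.empty(100)
        for tr, te in kf.split(y):
            resid[te] = y[te] - y[tr].mean()
        val = np.sqrt(np.mean(resid**2))
        assert val == pytest.approx(y.std(), rel=0.10)


class TestResidualTable:
    def test_perfect_model(self):
        out = residual_table(np.array([0.1, 0.5]), np.array([0.1, 0.5]))
        np.testing.assert_array_equal(out["residual"], [0.0, 0.0])
        assert out["mean_residual"] == 0.0

    def test_constant_overprediction(self, rng):
        y = rng.uniform(size=20)
        out = residual_table(y + 0.1, y)
        assert out["mean_residual"] == pytest.approx(0.1)

    def test_u_shape_detectable(self, rng):
        """A linear fit to a quadratic response leaves curvature in the
        residuals: |residual| grows with distance from the median target."""
        y = np.linspace(0, 1, 60)
        response = (y - 0.5) ** 2
        coef = np.polyfit(y, response, 1)
        pred = np.polyval(coef, y)
        out = residual_table(pred, response)
        from scipy.stats import spearmanr

        dist = np.abs(y - np.median(y))
        corr = spearmanr(np.abs(pred - response), dist).statistic
        assert abs(corr) > 0


class TestEvalReportInvariants:
    def test_rpd_rmsep_identity_enforced_by_construction(self, rng):
        y = rng.uniform(size=30)
        p = y + rng.normal(scale=0.05, size=30)
        assert rpd(y, p) * rmse(y, p) == pytest.approx(y.std(ddof=1), abs=1e-10)

    def test_negative_rmse_rejected(self):
        with pytest.raises(ValueError):
            EvalReport(model="m", strategy="raw", scope="combined",
                       rc2=0.9, rmsecv=0.1, rp2=0.9, rmsep=-0.1, rpd=1.0)


def _fast_experiment_config(**overrides):
    defaults = dict(
        simulator_seed=0,
        models=("plsr",),
        strategies=("raw",),
        scopes=("combined",),
        compute_rmsecv=False,
        seed=0,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


class TestRunExperiment:
    def test_matrix_size_three_models(self, monkeypatch):
        self._patch_small_sim(monkeypatch)
        cfg = _fast_experiment_config(models=("plsr", "svr"))
        reports = run_experiment(cfg)
        assert len(reports) == 2
        assert {r.model for r in reports} == {"plsr", "svr"}

    def test_variant_expansion(self, monkeypatch):
        self._patch_small_sim(monkeypatch)
        net_cfg = NetConfig(stem_filters=4, inception1=InceptionSpec(2, 2, 2, 2),
                            inception2=InceptionSpec(2, 2, 2, 2), fc_units=8,
                            max_epochs=2, patience=2)
        cfg = _fast_experiment_config(models=("incepspect_cbam",),
                                      variants=("full", "no_cbam"),
                                      net_config=net_cfg)
        reports = run_experiment(cfg)
        assert [r.model for r in reports] == ["incepspect_cbam",
                                              "incepspect_cbam:no_cbam"]

    def test_scope_expansion(self, monkeypatch):
        self._patch_small_sim(monkeypatch)
        cfg = _fast_experiment_config(scopes=("corn_flour", "combined"))
        reports = run_experiment(cfg)
        assert [r.scope for r in reports] == ["corn_flour", "combined"]

    def test_cell_failure_recorded_not_fatal(self, monkeypatch):
        self._patch_small_sim(monkeypatch)
        cfg = _fast_experiment_config(models=("plsr", "svr"),
                                      scopes=("combined",))
        import incepspect.evaluate as ev

        original = ev._fit_predictor

        def failing(model, cal, seed, net_config):
            if model == "svr":
                raise RuntimeError("boom")
            return original(model, cal, seed, net_config)

        monkeypatch.setattr(ev, "_fit_predictor", failing)
        reports = run_experiment(cfg)
        assert len(reports) == 2
        failed = [r for r in reports if "error" in r.extra]
        assert len(failed) == 1 and failed[0].model == "svr"

    def test_deterministic_rerun(self, monkeypatch):
        self._patch_small_sim(monkeypatch)
        cfg = _fast_experiment_config(models=("plsr",))
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert a[0].rmsep == b[0].rmsep
        assert a[0].rp2 == b[0].rp2

    @staticmethod
    def _patch_small_sim(monkeypatch):
        """Shrink the simulated dataset so harness tests stay fast."""
        import incepspect.evaluate as ev
        from incepspect.simulate import MixtureDesign, NoiseModel, simulate_dataset
        from incepspect.spectra_core import WavelengthGrid

        def small_load(config):
            design = MixtureDesign(
                levels=tuple(np.round(np.linspace(0, 1, 7), 3)),
                adulterants=("corn_flour", "wheat_bran"),
                replicates_per_level=3,
            )
            return simulate_dataset(design, NoiseModel(seed=config.simulator_seed),
                                    WavelengthGrid(np.linspace(1000, 2400, 30)))

        monkeypatch.setattr(ev, "_load_data", small_load)
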