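import numpy as np
import pandas as pd
import pytest

import phylocausal as pc
from phylocausal.glmm import (
    ConvergenceError,
    fit_glmm,
    haversine_matrix,
    kfold_compare,
    matern_covariance,
    refit_path_models,
    sample_polya_gamma,
    spatial_correlation,
    _fold_assignments,
)
from phylocausal.regression import chol_with_jitter
from phylocausal.simulate import MaternParams


class TestHaversine:
    def _locs(self, rows):
        return pd.DataFrame(rows, columns=["latitude", "longitude"])

    def test_identical_points_zero(self):
        d = haversine_matrix(self._locs([(10.0, 20.0), (10.0, 20.0)]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_half_circumference(self):
        d = haversine_matrix(self._locs([(0.0, 0.0), (0.0, 180.0)]))
        assert d[0, 1] == pytest.approx(20015.0, abs=1.0)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(0)
        locs = self._locs(list(zip(rng.uniform(-80, 80, 20),
                                   rng.uniform(-179, 179, 20))))
        d = haversine_matrix(locs)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestMatern:
    def test_zero_distance_returns_sigma2(self):
        D = np.zeros((2, 2))
        C = matern_covariance(D, MaternParams(phi=1.25, kappa=1.0, sigma2=2.5))
        assert np.allclose(C, 2.5)

    def test_exponential_special_case(self):
        """kappa = 1/2 reduces the Matérn to sigma2 * exp(-d/phi)."""
        d = np.array([[0.0, 0.7, 2.0], [0.7, 0.0, 1.1], [2.0, 1.1, 0.0]])
        C = matern_covariance(d, MaternParams(phi=0.9, kappa=0.5, sigma2=1.3))
        assert np.allclose(C, 1.3 * np.exp(-d / 0.9), atol=1e-8)

    def test_bessel_value_at_phi(self):
        # kappa=1, d=phi: correlation is K_1(1) ~ 0.6019
        d = np.array([[0.0, 1.25], [1.25, 0.0]])
        C = matern_covariance(d, MaternParams(phi=1.25, kappa=1.0, sigma2=1.0))
        assert C[0, 1] == pytest.approx(0.6019, abs=1e-3)

    def test_monotone_decreasing_in_distance(self):
        grid = np.linspace(0.0, 10.0, 60)
        D = np.abs(np.subtract.outer(grid, grid))
        C = matern_covariance(D, MaternParams())
        row = C[0]
        assert np.all(np.diff(row) <= 1e-12)

    def test_default_scaling_kills_correlation_by_1000km(self):
        """phi = 1.25, kappa = 1, distances in units of 200 km: correlation
        drops below 0.05 by ~1000 km while staying substantial at 200 km."""
        locs = pd.DataFrame({
            "latitude": [0.0, 0.0, 0.0],
            "longitude": [0.0, 200.0 / 111.32, 1050.0 / 111.32],
        })
        C = spatial_correlation(locs)
        assert C[0, 1] > 0.4
        assert C[0, 2] < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MaternParams(phi=-1.0)


class TestPolyaGamma:
    @pytest.mark.parametrize("c", [0.0, 0.8, 2.5])
    def test_mean_matches_tanh_formula(self, c):
        rng = np.random.default_rng(4)
        draws = sample_polya_gamma(np.full(60000, c), rng)
        expected = 0.25 if c == 0 else np.tanh(c / 2) / (2 * c)
        assert draws.mean() == pytest.approx(expected, rel=0.02)
        assert np.all(draws > 0)


class TestFitGLMM:
    def test_reduction_to_plain_logistic_without_effects(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(-0.5 + x)))).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_glmm(y, X, random_effects=(), chains=2, warmup=400,
                       draws=400, seed=5, check_convergence=False)
        ref = sm.Logit(y, X).fit(disp=0)
        for name in ("intercept", "x"):
            row = fit.fixed_effect(name)
            assert abs(row["mean"] - ref.params[name]) < 3 * ref.bse[name]
            assert row["q2.5"] <= row["mean"] <= row["q97.5"]

    def test_posterior_prevalence_matches_observed(self, tree200):
        """Posterior predictive prevalence of an intercept-only fit tracks
        the observed prevalence."""
        corr = tree200.correlation_matrix()
        y = pc.simulate_threshold_binary(tree200, 0.35, seed=3)
        X = pd.DataFrame({"intercept": np.ones(200)})
        fit = fit_glmm(y, X, random_effects=("phylo",), corr_phylo=corr,
                       chains=2, warmup=400, draws=400, seed=6,
                       check_convergence=False)
        beta = fit.posterior["beta"][:, :, 0].reshape(-1)
        u = fit.posterior["u_phylo"].reshape(-1, 200)
        prev = 1 / (1 + np.exp(-(beta[:, None] + u)))
        assert prev.mean() == pytest.approx(y.mean(), abs=0.08)

    def test_seed_determinism(self, tree200):
        corr = tree200.correlation_matrix()
        y = pc.simulate_threshold_binary(tree200, 0.4, seed=9)
        X = pd.DataFrame({"intercept": np.ones(200)})
        kw = dict(random_effects=("phylo",), corr_phylo=corr, chains=1,
                  warmup=50, draws=50, seed=42, check_convergence=False)
        f1 = fit_glmm(y, X, **kw)
        f2 = fit_glmm(y, X, **kw)
        assert np.array_equal(f1.posterior["beta"], f2.posterior["beta"])
        assert np.array_equal(f1.posterior["sigma_phylo"],
                              f2.posterior["sigma_phylo"])

    def test_convergence_gate_raises_with_diagnostics(self, tree200):
        corr = tree200.correlation_matrix()
        y = pc.simulate_threshold_binary(tree200, 0.4, seed=10)
        X = pd.DataFrame({"intercept": np.ones(200)})
        with pytest.raises(ConvergenceError) as err:
            # absurdly strict ESS requirement forces the gate to trip
            fit_glmm(y, X, random_effects=("phylo",), corr_phylo=corr,
                     chains=2, warmup=50, draws=50, seed=11,
                     min_ess=1e9, rhat_threshold=1.0)
        assert err.value.diagnostics is not None

    def test_misaligned_matrix_rejected(self):
        y = np.array([0.0, 1.0, 0.0])
        X = pd.DataFrame({"intercept": np.ones(3)})
        with pytest.raises(ValueError, match="aligned"):
            fit_glmm(y, X, random_effects=("phylo",), corr_phylo=np.eye(4),
                     chains=1, warmup=10, draws=10, seed=0)

    def test_missing_matrix_rejected(self):
        y = np.array([0.0, 1.0, 0.0])
        X = pd.DataFrame({"intercept": np.ones(3)})
        with pytest.raises(ValueError, match="no matrix"):
            fit_glmm(y, X, random_effects=("spatial",), chains=1,
                     warmup=10, draws=10, seed=0)


class TestKfold:
    def test_fold_partition(self):
        rng = np.random.default_rng(1)
        folds = _fold_assignments(53, 10, rng)
        assert len(folds) == 53
        counts = np.bincount(folds, minlength=10)
        assert counts.sum() == 53
        assert counts.max() - counts.min() <= 1

    def test_k_larger_than_n_rejected(self):
        y = np.array([0.0, 1.0])
        X = np.ones((2, 1))
        with pytest.raises(ValueError, match="K cannot exceed"):
            kfold_compare(y, X, {"m": ()}, K=5, seed=0)

    def test_self_comparison_is_equivalent(self, tree200):
        """A model compared with itself differs by Monte-Carlo noise only."""
        corr = tree200.correlation_matrix()
        y = pc.simulate_threshold_binary(tree200, 0.4, seed=14)
        X = pd.DataFrame({"intercept": np.ones(200)})
        kt = kfold_compare(
            y, X, {"m1": ("phylo",), "m2": ("phylo",)},
            corr_phylo=corr, K=4, seed=3, chains=1, warmup=150, draws=150)
        pair = kt.pairs.iloc[0]
        assert bool(pair["equivalent"])

    def test_discriminates_generating_structure(self):
        """With strongly phylogenetic data, the phylo-only model out-predicts
        the spatial-only model."""
        rng = np.random.default_rng(0)
        wins = 0
        for r in range(2):
            n = 120
            tree = pc.simulate_tree(n, seed=200 + r)
            corr = tree.correlation_matrix()
            coords = pc.simulate_coordinates(n, seed=300 + r)
            corr_sp = spatial_correlation(coords)
            L = chol_with_jitter(corr)
            u = 2.0 * (L @ rng.standard_normal(n))
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.2 + u)))).astype(float)
            X = pd.DataFrame({"intercept": np.ones(n)})
            kt = kfold_compare(
                y, X, {"phylo": ("phylo",), "spatial": ("spatial",)},
                corr_phylo=corr, corr_spatial=corr_sp, K=10, seed=40 + r,
                chains=1, warmup=250, draws=250)
            wins += kt.elpd["phylo"] > kt.elpd["spatial"]
        assert wins == 2


class TestRefits:
    def test_model_c_refit_recovers_verb_final_to_case(self):
        scen = pc.scenario("model_c", n_tips=150, seed=42)
        tree, traits, _ = pc.simulate_dataset(scen, with_coordinates=False)
        corr = tree.correlation_matrix()
        bcd = {"c": pc.paper_model_set()["c"]}
        out = refit_path_models(traits, corr, bcd, chains=2, warmup=300,
                                draws=300, seed=1, check_convergence=False)
        row = out[(out["source"] == "verb_final") & (out["target"] == "case")]
        assert len(row) == 1
        assert row["mean"].iloc[0] > 0
        assert not row["includes_zero"].iloc[0]

    def test_null_data_paths_include_zero(self, null_dataset):
        tree, traits, _ = null_dataset
        corr = tree.correlation_matrix()
        bcd = {"c": pc.paper_model_set()["c"]}
        out = refit_path_models(traits, corr, bcd, chains=2, warmup=300,
                                draws=300, seed=2, check_convergence=False)
        assert out["includes_zero"].all()
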