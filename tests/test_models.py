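import warnings

import numpy as np
import pandas as pd
import pytest

from geoconverge.models import (
    ModelSpec,
    fit,
    fit_random_effects,
    hausman_test,
    lr_test,
    panel_arrays,
    within_transform,
)
from geoconverge.regions import make_lattice_map
from geoconverge.synthetic import DGPConfig, simulate_sdm_panel
from geoconverge.weights import row_standardize, weights_from_edges


def small_panel(seed, rows=3, cols=4, n_years=6, rho=0.3, k=2, sigma2=0.05):
    m = make_lattice_map(rows, cols)
    w = row_standardize(weights_from_edges(m))
    dgp = DGPConfig(
        rho_true=rho, beta_true=np.ones(k), theta_true=0.1 * np.ones(k),
        sigma2_true=sigma2, n_years=n_years, seed=seed,
    )
    return simulate_sdm_panel(m, dgp), w, [f"x{j + 1}" for j in range(k)]


class TestWithinTransform:
    def test_none_is_identity(self):
        a = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(within_transform(a, "none"), a)

    def test_constant_column_zeroed_by_individual_demeaning(self):
        a = np.tile([[3.0], [5.0]], (1, 4))
        assert np.allclose(within_transform(a, "individual"), 0.0)

    def test_additive_two_by_two_panel_vanishes_under_twoway(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])  # perfectly additive in i and t
        assert np.allclose(within_transform(a, "twoway"), 0.0, atol=1e-14)

    def test_demeaned_dimensions_are_mean_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 7))
        ind = within_transform(a, "individual")
        tw = within_transform(a, "twoway")
        assert np.allclose(ind.mean(axis=1), 0.0, atol=1e-14)
        assert np.allclose(tw.mean(axis=0), 0.0, atol=1e-14)
        assert np.allclose(tw.mean(axis=1), 0.0, atol=1e-14)

    def test_unbalanced_panel_rejected(self):
        panel = pd.DataFrame(
            {"region": ["a", "a", "b"], "year": [1, 2, 1], "y": [1.0, 2, 3], "x": [1.0, 1, 1]}
        )
        with pytest.raises(ValueError, match="unbalanced"):
            panel_arrays(panel, "y", ["x"], ("a", "b"))


class TestFit:
    def test_noiseless_identity_recovers_beta_exactly(self, lattice30, w30_std):
        dgp = DGPConfig(rho_true=0.0, beta_true=np.array([1.0]), sigma2_true=0.0,
                        fe_individual_sd=0.0, fe_time_sd=0.0, n_years=4, seed=3)
        panel = simulate_sdm_panel(lattice30, dgp)
        with pytest.warns(UserWarning, match="unidentified"):
            res = fit(ModelSpec("SDM", "y", ["x1"], effects="none"), panel, w30_std)
        assert res.rho == pytest.approx(0.0, abs=1e-6)
        assert res.beta["x1"] == pytest.approx(1.0, abs=1e-6)

    def test_concentrated_likelihood_beats_grid(self):
        """Optimized log-likelihood is at least the best of a 201-point grid."""
        for seed in range(20):
            panel, w, xv = small_panel(seed)
            res = fit(ModelSpec("SLM", "y", xv), panel, w)
            lo, hi = res.rho_interval
            grid = np.linspace(lo + 1e-4, hi - 1e-4, 201)
            grid_ll = [
                fit(ModelSpec("SLM", "y", xv), panel, w, rho_fixed=r).loglik for r in grid
            ]
            assert res.loglik >= max(grid_ll) - 1e-8

    def test_slm_parameter_recovery(self, lattice30, w30_std):
        rhos = []
        for seed in range(30):
            dgp = DGPConfig(rho_true=0.4, beta_true=np.array([1.0]), theta_true=np.array([0.0]),
                            sigma2_true=0.04, n_years=18, seed=seed)
            panel = simulate_sdm_panel(lattice30, dgp)
            res = fit(ModelSpec("SLM", "y", ["x1"]), panel, w30_std)
            rhos.append(res.rho)
        assert abs(np.mean(rhos) - 0.4) < 0.05

    def test_sem_recovers_spatial_error_parameter(self, lattice30, w30_std):
        rng = np.random.default_rng(0)
        n, T, lam = 30, 18, 0.5
        a_inv = np.linalg.inv(np.eye(n) - lam * w30_std.matrix)
        lams = []
        for _ in range(20):
            x = rng.normal(size=(n, T))
            u = np.stack([a_inv @ rng.normal(0, 0.2, size=n) for _ in range(T)], axis=1)
            y = 1.5 * x + u
            panel = pd.DataFrame({
                "region": np.repeat(list(w30_std.region_order), T),
                "year": list(range(T)) * n, "y": y.ravel(), "x1": x.ravel(),
            })
            res = fit(ModelSpec("SEM", "y", ["x1"], effects="individual"), panel, w30_std)
            lams.append(res.lam)
        assert abs(np.mean(lams) - lam) < 0.07

    def test_vcov_symmetric_psd(self):
        panel, w, xv = small_panel(1)
        for fam in ("FE", "SLM", "SEM", "SDM"):
            res = fit(ModelSpec(fam, "y", xv), panel, w)
            v = res.vcov.to_numpy()
            assert np.allclose(v, v.T, atol=1e-10)
            assert np.linalg.eigvalsh((v + v.T) / 2).min() > -1e-10
            assert res.sigma2 > 0

    def test_loglik_smooth_over_admissible_interval(self):
        panel, w, xv = small_panel(2)
        lo, hi = fit(ModelSpec("SLM", "y", xv), panel, w).rho_interval
        for r in np.linspace(lo + 1e-3, hi - 1e-3, 40):
            ll = fit(ModelSpec("SLM", "y", xv), panel, w, rho_fixed=r).loglik
            assert np.isfinite(ll)

    def test_log_transform_requires_positive_values(self, lattice30, w30_std):
        dgp = DGPConfig(seed=0, n_years=3)
        panel = simulate_sdm_panel(lattice30, dgp)  # y takes both signs
        with pytest.raises(ValueError, match="strictly positive"):
            fit(ModelSpec("SLM", "y", ["x1"], log_transform=True), panel, w30_std)

    def test_unstandardized_weights_rejected(self, lattice30):
        panel = simulate_sdm_panel(lattice30, DGPConfig(seed=0, n_years=3))
        w_bin = weights_from_edges(lattice30)
        with pytest.raises(ValueError, match="row-standardized"):
            fit(ModelSpec("SLM", "y", ["x1"]), panel, w_bin)


class TestReductions:
    def test_sdm_with_zero_theta_equals_slm(self):
        for seed in range(5):
            panel, w, xv = small_panel(seed)
            sdm0 = fit(ModelSpec("SDM", "y", xv), panel, w, theta_zero=True)
            slm = fit(ModelSpec("SLM", "y", xv), panel, w)
            assert sdm0.rho == pytest.approx(slm.rho, abs=1e-8)
            assert np.allclose(sdm0.beta, slm.beta, atol=1e-8)
            assert sdm0.loglik == pytest.approx(slm.loglik, abs=1e-8)

    def test_slm_with_zero_rho_equals_fe_least_squares(self):
        for seed in range(5):
            panel, w, xv = small_panel(seed)
            slm0 = fit(ModelSpec("SLM", "y", xv), panel, w, rho_fixed=0.0)
            fe = fit(ModelSpec("FE", "y", xv), panel, w)
            assert np.allclose(slm0.beta, fe.beta, atol=1e-8)


class TestLrTest:
    def test_identical_fits_give_zero_statistic(self):
        panel, w, xv = small_panel(0)
        sdm = fit(ModelSpec("SDM", "y", xv), panel, w)
        res = lr_test(sdm, sdm, df=len(xv))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_non_nested_pair_rejected(self):
        panel, w, xv = small_panel(0)
        slm = fit(ModelSpec("SLM", "y", xv), panel, w)
        sem = fit(ModelSpec("SEM", "y", xv), panel, w)
        with pytest.raises(ValueError, match="nested"):
            lr_test(slm, sem, df=1)

    def test_power_against_nonzero_theta(self, lattice30, w30_std):
        """Strong spatial-lag coefficients are detected at n=30, T=18."""
        rej = 0
        for seed in range(20):
            dgp = DGPConfig(rho_true=0.24, beta_true=np.array([0.58]),
                            theta_true=np.array([0.5]), sigma2_true=0.01,
                            n_years=18, seed=seed)
            panel = simulate_sdm_panel(lattice30, dgp)
            sdm = fit(ModelSpec("SDM", "y", ["x1"]), panel, w30_std)
            slm = fit(ModelSpec("SLM", "y", ["x1"]), panel, w30_std)
            rej += lr_test(sdm, slm).p < 0.05
        assert rej / 20 > 0.5


class TestHausman:
    def test_identical_estimates_give_zero(self):
        panel, w, xv = small_panel(0)
        fe = fit(ModelSpec("FE", "y", xv, effects="individual"), panel, w)
        re = fit_random_effects(panel, "y", xv)
        # force identity: compare FE with itself through the RE container
        re.beta = fe.beta.copy()
        re.vcov = fe.vcov.loc[xv, xv] * 0.5
        res = hausman_test(fe, re)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_detects_effects_correlated_with_regressors(self, lattice30):
        """FE and RE diverge when individual effects track the regressors."""
        rng = np.random.default_rng(21)
        n, T = 30, 18
        xbar = rng.normal(size=n)
        x = xbar[:, None] + rng.normal(0, 0.5, size=(n, T))
        mu = 2.0 * xbar + rng.normal(0, 0.1, size=n)  # strongly correlated effects
        y = 1.0 * x + mu[:, None] + rng.normal(0, 0.2, size=(n, T))
        panel = pd.DataFrame({
            "region": np.repeat(list(lattice30.region_ids), T),
            "year": list(range(T)) * n, "y": y.ravel(), "x1": x.ravel(),
        })
        fe = fit(ModelSpec("FE", "y", ["x1"], effects="individual"), panel)
        re = fit_random_effects(panel, "y", ["x1"])
        res = hausman_test(fe, re)
        assert res.p < 0.05

    def test_size_under_uncorrelated_effects(self, lattice30):
        """RE-consistent data rarely rejects."""
        rng = np.random.default_rng(22)
        n, T = 30, 10
        rej = 0
        reps = 40
        for _ in range(reps):
            x = rng.normal(size=(n, T))
            mu = rng.normal(0, 0.5, size=n)  # independent of x
            y = 1.0 * x + mu[:, None] + rng.normal(0, 0.3, size=(n, T))
            panel = pd.DataFrame({
                "region": np.repeat(list(lattice30.region_ids), T),
                "year": list(range(T)) * n, "y": y.ravel(), "x1": x.ravel(),
            })
            fe = fit(ModelSpec("FE", "y", ["x1"], effects="individual"), panel)
            re = fit_random_effects(panel, "y", ["x1"])
            with warnings.catch_warnings():
                # FE and RE are both consistent here, so the variance
                # difference is often numerically indefinite
                warnings.simplefilter("ignore")
                rej += hausman_test(fe, re).p < 0.05
        assert rej / reps < 0.2
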