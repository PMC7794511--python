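"""Likelihood, linear predictor, GP kernel, and log-posterior correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb, expit

from pinemort.design import DESIGN_COLUMNS, N_BETA
from pinemort.model import (
    ZibGpModel,
    gp_covariance,
    linear_predictor,
    safe_cholesky,
    zib_logpmf,
    zib_rvs,
)
from pinemort.synthetic import SyntheticConfig, generate_landscape


class TestZibLogpmf:
    def test_worked_mixture_value(self):
        # log(p + (1-p) (1-pi)^n) = log(0.2 + 0.8 * 0.25)
        assert zib_logpmf(0, 2, 0.5, 0.2) == pytest.approx(np.log(0.4))

    def test_collapses_to_binomial_when_p_zero(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            y = int(rng.integers(0, n + 1))
            pi = rng.uniform(0.01, 0.99)
            assert zib_logpmf(y, n, pi, 0.0) == pytest.approx(
                stats.binom.logpmf(y, n, pi), rel=1e-12
            )

    def test_normalizes_to_one(self, rng):
        """Brute-force normalization oracle over the full support."""
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(0, 31))
            pi = rng.uniform(0, 1)
            p = rng.uniform(0, 1)
            total = np.sum(np.exp(zib_logpmf(np.arange(n + 1), n, pi, p)))
            worst = max(worst, abs(total - 1.0))
        assert worst < 1e-12

    def test_y_above_n_rejected(self):
        with pytest.raises(ValueError):
            zib_logpmf(3, 2, 0.5, 0.1)

    def test_moves_away_from_expectation_lose_mass(self):
        n, pi = 30, 0.4
        center = int(round(n * pi))
        lp = [float(zib_logpmf(y, n, pi, 0.1)) for y in range(1, n + 1)]
        # unimodal away from the zero spike: decreasing on both sides of n*pi
        assert all(np.diff(lp[center - 1:]) < 0)
        assert all(np.diff(lp[: center - 1]) > 0)

    def test_rvs_zero_probability_matches_closed_form(self, rng):
        n, pi, p = 5, 0.3, 0.2
        draws = zib_rvs(np.full(40000, n), pi, p, rng)
        target = p + (1 - p) * (1 - pi) ** n
        se = np.sqrt(target * (1 - target) / draws.size)
        assert abs((draws == 0).mean() - target) < 4 * se


class TestLinearPredictor:
    def test_intercept_only(self):
        X = np.zeros((3, N_BETA))
        X[:, 0] = 1.0
        beta = np.zeros(N_BETA)
        beta[0] = 0.5
        np.testing.assert_allclose(linear_predictor(beta, X), 0.5)

    def test_cwd_dot_product(self):
        X = np.zeros((1, N_BETA))
        X[0, 0], X[0, 1] = 1.0, 2.0  # X_cwd = 2
        beta = np.zeros(N_BETA)
        beta[0], beta[1] = 0.5, 1.0
        assert linear_predictor(beta, X)[0] == pytest.approx(2.5)

    def test_three_way_single_term(self):
        # only b13 nonzero; cwd = propHost = height = 1 makes the product 1
        X = np.zeros((1, N_BETA))
        X[0, 0] = 1.0
        X[0, 13] = 1.0
        beta = np.zeros(N_BETA)
        beta[13] = 0.2
        assert linear_predictor(beta, X)[0] == pytest.approx(0.2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor(np.zeros(N_BETA), np.zeros((2, 5)))


class TestGpKernel:
    def test_diagonal_and_reference_distance(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        K = gp_covariance(coords, gp_sd=1.0, gp_lengthscale=10.0)
        assert K[0, 0] == pytest.approx(1.0 + 1e-8)
        assert K[0, 1] == pytest.approx(np.exp(-0.5))

    def test_sd_scaling(self):
        coords = np.array([[0.0, 0.0], [5.0, 5.0]])
        K1 = gp_covariance(coords, 1.0, 20.0)
        K2 = gp_covariance(coords, 3.0, 20.0)
        np.testing.assert_allclose(K2, 9.0 * K1)

    def test_positive_definite_random_coords(self, rng):
        """Cholesky oracle on random coordinate sets up to n = 200."""
        for n in [5, 50, 200]:
            coords = rng.uniform(0, 300, size=(n, 2))
            K = gp_covariance(coords, gp_sd=1.3, gp_lengthscale=35.0)
            L = safe_cholesky(K)
            np.testing.assert_allclose(L @ L.T, K, atol=1e-8)

    def test_invalid_hyperparameters(self):
        coords = np.zeros((2, 2))
        with pytest.raises(ValueError):
            gp_covariance(coords, -1.0, 10.0)
        with pytest.raises(ValueError):
            gp_covariance(coords, 1.0, 0.0)

    def test_sample_covariance_converges_to_kernel(self, rng):
        """Replicate whitened draws reproduce the kernel matrix (<= 25 cells)."""
        coords = rng.uniform(0, 100, size=(16, 2))
        K = gp_covariance(coords, gp_sd=0.8, gp_lengthscale=30.0)
        L = safe_cholesky(K)
        draws = (L @ rng.standard_normal((16, 4000))).T
        emp = np.cov(draws, rowvar=False)
        assert np.max(np.abs(emp - K)) < 6 * 0.8**2 / np.sqrt(4000) * 3


def tiny_table(cells_per_site=5, seed=4):
    cfg = SyntheticConfig(
        n_sites=2, cells_per_site=cells_per_site, grid_side_cells=4, seed=seed
    )
    return generate_landscape(cfg).model_table()


class TestLogPosterior:
    def test_matches_naive_implementation(self, rng):
        """Differences of log posterior agree with a naive non-log-space
        oracle (direct pmf products, direct prior densities) to 1e-8."""
        table = tiny_table()
        model = ZibGpModel(table)

        def naive_lp(params):
            beta = params["beta"]
            p = params["zi_p"]
            z = params["gp_z"]
            gp = np.zeros(len(table))
            pos = 0
            for j, site in enumerate(model.sites):
                nj = len(site.idx)
                coords = table.loc[site.idx, ["centroid_x_m", "centroid_y_m"]].to_numpy()
                K = gp_covariance(coords, 1.0, params["gp_lengthscale"][j])
                Lc = np.linalg.cholesky(K)  # correlation + jitter
                gp[site.idx] = params["gp_sd"][j] * (Lc @ z[pos : pos + nj])
                pos += nj
            X = np.column_stack(
                [np.ones(len(table))] + [table[c] for c in DESIGN_COLUMNS]
            )
            pi = expit(X @ beta + gp)
            y = table["y_dead"].to_numpy()
            n = table["n_host"].to_numpy()
            like = np.where(
                y == 0,
                p + (1 - p) * (1 - pi) ** n,
                (1 - p) * comb(n, y) * pi**y * (1 - pi) ** (n - y),
            )
            lp = float(np.sum(np.log(like)))
            lp += float(np.sum(np.log(stats.norm.pdf(z))))
            lp += float(stats.t.logpdf(beta[0], df=3, scale=2.5))
            lp += float(np.sum(stats.norm.logpdf(beta[1:], scale=5.0)))
            # p ~ U(0,1) on the logit scale: Jacobian p(1-p)
            lp += float(np.log(p * (1 - p)))
            for j, site in enumerate(model.sites):
                sd, ls = params["gp_sd"][j], params["gp_lengthscale"][j]
                # half-t on sd with log-scale Jacobian
                lp += float(np.log(2 * stats.t.pdf(sd, df=3, scale=2.5) * sd))
                # inverse-gamma(5, 4*ls0) on ls with log-scale Jacobian
                lp += float(
                    stats.invgamma.logpdf(ls, 5.0, scale=4.0 * site.ls0) + np.log(ls)
                )
            return lp

        def rand_params():
            J = model.n_sites
            return {
                "beta": rng.normal(0, 0.5, N_BETA),
                "zi_p": rng.uniform(0.05, 0.4),
                "gp_sd": rng.uniform(0.2, 1.0, J),
                "gp_lengthscale": rng.uniform(20, 60, J),
                "gp_z": rng.normal(0, 1, model.n_cells),
            }

        p1, p2 = rand_params(), rand_params()
        mine = model.log_posterior(p1) - model.log_posterior(p2)
        ref = naive_lp(p1) - naive_lp(p2)
        assert mine == pytest.approx(ref, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        table = tiny_table(cells_per_site=4, seed=6)
        model = ZibGpModel(table)
        theta = model.initial_theta(rng, jitter=0.3)
        lp, g = model.logp_and_grad(theta)
        assert np.isfinite(lp)
        eps = 1e-6
        for k in range(0, model.dim, 3):
            up, dn = theta.copy(), theta.copy()
            up[k] += eps
            dn[k] -= eps
            fd = (model.logp_and_grad(up)[0] - model.logp_and_grad(dn)[0]) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_worse_fit_lowers_posterior(self):
        """Moving an observed count away from its expectation, everything else
        fixed, must reduce the log posterior."""
        table = tiny_table()
        model = ZibGpModel(table, include_gp=False, zero_inflation=False)
        params = {"beta": np.zeros(N_BETA)}  # pi = 0.5 everywhere
        base = model.log_posterior(params)
        worse = table.copy()
        i = worse.index[worse["n_host"] >= 4][0]
        worse.loc[i, "y_dead"] = 0
        worse.loc[i, "n_host"] = 30  # y far below expectation 15
        model_worse = ZibGpModel(worse, include_gp=False, zero_inflation=False)
        assert model_worse.log_posterior(params) < base

    def test_pack_unpack_round_trip(self, rng):
        model = ZibGpModel(tiny_table())
        theta = model.initial_theta(rng, jitter=0.2)
        packed = model.pack(model.unpack(theta))
        np.testing.assert_allclose(packed, theta, atol=1e-12)
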