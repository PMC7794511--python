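"""MAP fits, MCMC mechanics, effect summaries, posterior predictive checks."""

import numpy as np
import pandas as pd
import pytest

from pinemort.design import COEFFICIENT_NAMES, N_BETA
from pinemort.model import (
    fit_map,
    fit_model,
    posterior_predictive_check,
    summarize_effects,
)
from pinemort.synthetic import SyntheticConfig, generate_landscape


def glm_limit_table(n_sites=2, cells=60, seed=21):
    cfg = SyntheticConfig(
        n_sites=n_sites, cells_per_site=cells, grid_side_cells=9,
        zi_p=0.0, gp_sd=0.0, seed=seed,
    )
    return generate_landscape(cfg).model_table()


class TestMap:
    def test_matches_binomial_glm_oracle(self):
        """With no GP and no zero inflation, the flat-prior MAP is the
        binomial-GLM maximum likelihood (independent IRLS oracle)."""
        import statsmodels.api as sm

        table = glm_limit_table()
        beta = fit_map(table, flat_priors=True)["beta"]
        from pinemort.design import design_matrix

        X = design_matrix(table)
        endog = np.column_stack([table["y_dead"], table["n_host"] - table["y_dead"]])
        ref = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-4)

    def test_priors_shrink_map_toward_zero(self):
        table = glm_limit_table()
        flat = fit_map(table, flat_priors=True)["beta"]
        reg = fit_map(table, flat_priors=False)["beta"]
        assert np.sum(reg**2) <= np.sum(flat**2) + 1e-9

    def test_zero_inflation_recovered_at_map(self):
        cfg = SyntheticConfig(n_sites=6, cells_per_site=150, grid_side_cells=13,
                              zi_p=0.3, gp_sd=0.0, seed=8)
        table = generate_landscape(cfg).model_table()
        est = fit_map(table, zero_inflation=True)
        assert est["zi_p"] == pytest.approx(0.3, abs=0.08)


class TestSummaries:
    def test_quantile_arithmetic(self):
        draws = np.arange(1, 101)[:, None] / 100.0
        out = summarize_effects(draws, names=["x"])
        assert out["median"].iloc[0] == pytest.approx(0.505)
        # linear interpolation between order statistics
        assert out["ci95_lo"].iloc[0] == pytest.approx(np.quantile(draws, 0.025))
        assert out["ci95_hi"].iloc[0] == pytest.approx(np.quantile(draws, 0.975))
        assert out["ci66_lo"].iloc[0] == pytest.approx(np.quantile(draws, 0.17))

    def test_symmetric_draws_center_on_zero(self, rng):
        draws = rng.normal(0, 1, size=(4000, 1))
        draws = np.concatenate([draws, -draws])  # exactly symmetric
        out = summarize_effects(draws, names=["x"])
        assert out["median"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["ci95_lo"].iloc[0] == pytest.approx(-out["ci95_hi"].iloc[0], rel=1e-9)
        assert not out["sign_certain"].iloc[0]

    def test_nested_intervals_and_names(self, small_landscape):
        fit = _tiny_fit(small_landscape)
        out = summarize_effects(fit)
        assert list(out["parameter"]) == COEFFICIENT_NAMES
        assert (out["ci95_lo"] <= out["ci66_lo"]).all()
        assert (out["ci66_hi"] <= out["ci95_hi"]).all()


_FIT_CACHE = {}


def _tiny_fit(landscape, seed=12):
    key = ("tiny", seed)
    if key not in _FIT_CACHE:
        _FIT_CACHE[key] = fit_model(
            landscape.model_table(), chains=2, warmup=150, draws=150, seed=seed,
            max_leapfrog=16,
        )
    return _FIT_CACHE[key]


class TestHmcFit:
    def test_shapes_metadata_and_diagnostics(self, small_landscape):
        fit = _tiny_fit(small_landscape)
        n_sites = len(fit.model.sites)
        assert fit.draws["beta"].shape == (2, 150, N_BETA)
        assert fit.draws["gp_sd"].shape == (2, 150, n_sites)
        assert fit.draws["zi_p"].shape == (2, 150)
        assert fit.meta["chains"] == 2
        diag = fit.diagnostics
        assert {"rhat", "ess_bulk", "ess_tail"} <= set(diag.columns)
        assert (diag["ess_bulk"] > 0).all()
        summ = fit.summary()
        assert "rhat" in summ.columns and len(summ) >= N_BETA + 1

    def test_seed_reproducibility(self, small_landscape):
        a = fit_model(small_landscape.model_table(), chains=1, warmup=60, draws=40,
                      seed=5, max_leapfrog=8)
        b = fit_model(small_landscape.model_table(), chains=1, warmup=60, draws=40,
                      seed=5, max_leapfrog=8)
        np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])

    def test_posterior_matches_prior_without_data(self, rng):
        """Cells with zero trials carry no likelihood: the sampled slope
        margins must reproduce the Normal(0, 5) prior."""
        table = pd.DataFrame(
            {
                "site_id": "s",
                "centroid_x_m": np.arange(4) * 20.0,
                "centroid_y_m": 0.0,
                "y_dead": 0,
                "n_host": 0,
            }
        )
        from pinemort.design import DESIGN_COLUMNS

        for c in DESIGN_COLUMNS:
            table[c] = 0.0
        fit = fit_model(table, chains=2, warmup=400, draws=600, seed=9,
                        include_gp=False, zero_inflation=False, max_leapfrog=24)
        slopes = fit.stacked("beta")[:, 1:]
        assert abs(slopes.mean()) < 0.6
        assert np.std(slopes) == pytest.approx(5.0, rel=0.15)


class TestPpc:
    def test_single_replicate_and_determinism(self, small_landscape):
        fit = _tiny_fit(small_landscape)
        one = posterior_predictive_check(fit, n_rep=1, seed=3)
        assert one["y_rep"].shape == (1, fit.model.n_cells)
        a = posterior_predictive_check(fit, n_rep=10, seed=3)
        b = posterior_predictive_check(fit, n_rep=10, seed=3)
        np.testing.assert_array_equal(a["y_rep"], b["y_rep"])

    def test_replicates_respect_trial_bounds(self, small_landscape):
        fit = _tiny_fit(small_landscape)
        out = posterior_predictive_check(fit, n_rep=20, seed=1)
        assert (out["y_rep"] >= 0).all()
        assert (out["y_rep"] <= fit.model.n[None, :]).all()
        assert 0.0 <= out["zero_fraction_obs"] <= 1.0


class TestSharedHyperAndIo:
    def test_shared_hyperparameter_mode(self, small_landscape):
        fit = fit_model(small_landscape.model_table(), chains=1, warmup=80, draws=60,
                        seed=4, shared_gp_hyper=True, max_leapfrog=8)
        assert fit.draws["gp_sd"].shape == (1, 60, 1)
        assert any(p == "gp_sd[shared]" for p in fit.summary()["parameter"])

    def test_fit_and_landscape_round_trip_to_disk(self, small_landscape, tmp_path):
        fit = _tiny_fit(small_landscape)
        fit.save(tmp_path / "fit")
        saved = pd.read_csv(tmp_path / "fit" / "draws_beta.csv")
        assert saved.shape == (2 * 150, N_BETA)
        assert (tmp_path / "fit" / "summary.csv").exists()
        small_landscape.write_csv(tmp_path / "sim")
        cells = pd.read_csv(tmp_path / "sim" / "cells.csv")
        assert len(cells) == len(small_landscape.cells)
        from pinemort.synthetic import SyntheticConfig

        assert SyntheticConfig.from_yaml(tmp_path / "sim" / "config.yaml") == \
            small_landscape.config
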