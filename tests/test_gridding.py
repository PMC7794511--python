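"""Tree-to-cell aggregation, covariate standardization, subsampling."""

import numpy as np
import pandas as pd
import pytest

from pinemort.gridding import rasterize_trees, standardize_covariates, subsample_cells


def one_cell_trees():
    # 2 live hosts (10, 20 m) + 1 dead (30 m) + 1 live non-host
    return pd.DataFrame(
        {
            "site_id": "s1",
            "x_m": [1.0, 5.0, 9.0, 12.0],
            "y_m": [1.0, 5.0, 9.0, 12.0],
            "host": [1, 1, 0, 0],
            "dead": [0, 0, 1, 0],
            "height_m": [10.0, 20.0, 30.0, 15.0],
            "ba_m2": [0.1, 0.2, 0.3, 0.1],
        }
    )


class TestRasterize:
    def test_dead_is_host_enumeration(self):
        cells = rasterize_trees(one_cell_trees(), origin=(0.0, 0.0))
        c = cells.iloc[0]
        assert c["n_total"] == 4
        assert c["n_host"] == 3  # 2 live hosts + 1 dead (assumed host)
        assert c["y_dead"] == 1
        assert c["prop_host"] == pytest.approx(0.75)
        assert c["mean_host_height_m"] == pytest.approx(20.0)
        assert c["total_ba_m2"] == pytest.approx(0.7)

    def test_live_only_host_mode(self):
        cells = rasterize_trees(one_cell_trees(), origin=(0.0, 0.0), dead_is_host=False)
        c = cells.iloc[0]
        assert c["n_host"] == 2
        assert c["mean_host_height_m"] == pytest.approx(15.0)

    def test_half_open_cell_convention(self):
        trees = pd.DataFrame({"x_m": [20.0], "y_m": [0.0], "host": [1], "dead": [0],
                              "height_m": [10.0], "ba_m2": [0.1]})
        cells = rasterize_trees(trees, origin=(0.0, 0.0))
        hit = cells.loc[cells["n_total"] > 0].iloc[0]
        assert (hit["cell_ix"], hit["cell_iy"]) == (1, 0)

    def test_empty_cells_emitted_and_flagged(self):
        trees = pd.DataFrame({"x_m": [5.0, 45.0], "y_m": [5.0, 45.0], "host": [1, 1],
                              "dead": [0, 0], "height_m": [10.0, 10.0], "ba_m2": [0.1, 0.1]})
        cells = rasterize_trees(trees, origin=(0.0, 0.0))
        assert len(cells) == 9  # 3x3 bounding grid
        empty = cells.loc[cells["n_total"] == 0]
        assert len(empty) == 7
        assert (~empty["eligible"]).all()
        assert empty["mean_host_height_m"].isna().all()

    def test_conservation_and_order_invariance(self, stem_map):
        trees = stem_map.assign(ba_m2=0.05, site_id="s")
        cells = rasterize_trees(trees, origin=(0.0, 0.0))
        assert cells["n_total"].sum() == len(trees)
        shuffled = trees.sample(frac=1.0, random_state=3)
        cells2 = rasterize_trees(shuffled, origin=(0.0, 0.0))
        pd.testing.assert_frame_equal(
            cells.sort_values(["cell_ix", "cell_iy"]).reset_index(drop=True),
            cells2.sort_values(["cell_ix", "cell_iy"]).reset_index(drop=True),
        )

    def test_translation_by_whole_cells(self, stem_map):
        trees = stem_map.assign(ba_m2=0.05, site_id="s")
        a = rasterize_trees(trees, origin=(0.0, 0.0))
        moved = trees.assign(x_m=trees["x_m"] + 40.0, y_m=trees["y_m"] + 60.0)
        b = rasterize_trees(moved, origin=(40.0, 60.0))
        np.testing.assert_allclose(
            a.sort_values(["cell_ix", "cell_iy"])["prop_host"].to_numpy(dtype=float),
            b.sort_values(["cell_ix", "cell_iy"])["prop_host"].to_numpy(dtype=float),
        )
        np.testing.assert_array_equal(
            a.sort_values(["cell_ix", "cell_iy"])["y_dead"].to_numpy(),
            b.sort_values(["cell_ix", "cell_iy"])["y_dead"].to_numpy(),
        )

    def test_out_of_extent_trees_dropped_with_count(self):
        trees = pd.DataFrame({"x_m": [5.0, 95.0], "y_m": [5.0, 95.0], "host": [1, 1],
                              "dead": [0, 0], "height_m": [10.0, 10.0], "ba_m2": [0.1, 0.1]})
        cells = rasterize_trees(trees, origin=(0.0, 0.0), shape=(2, 2))
        assert cells.attrs["n_dropped"] == 1
        assert cells["n_total"].sum() == 1


def toy_cells():
    return pd.DataFrame(
        {
            "site_id": ["a", "a", "b", "b"],
            "centroid_x_m": [10.0, 30.0, 10.0, 30.0],
            "centroid_y_m": [10.0, 10.0, 10.0, 10.0],
            "y_dead": [1, 0, 2, 1],
            "n_host": [4, 3, 5, 2],
            "n_total": [6, 5, 8, 4],
            "prop_host": [4 / 6, 3 / 5, 5 / 8, 2 / 4],
            "mean_host_height_m": [18.0, 22.0, 15.0, 27.0],
            "total_ba_m2": [1.2, 0.8, 1.5, 0.6],
        }
    )


def toy_sites():
    return pd.DataFrame({"site_id": ["a", "b"], "cwd_z": [-0.5, 0.9]})


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        tab, _ = standardize_covariates(toy_cells(), toy_sites())
        for col in ["z_prop_host", "z_host_height", "z_density", "z_ba"]:
            assert tab[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert tab[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_two_value_hand_arithmetic(self):
        cells = toy_cells().iloc[:2].copy()
        cells["total_ba_m2"] = [10.0, 20.0]
        cells["site_id"] = ["a", "b"]
        tab, _ = standardize_covariates(cells, toy_sites())
        np.testing.assert_allclose(
            tab["z_ba"].to_numpy(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_cwd_standardized_over_sites_and_replicated(self):
        tab, std = standardize_covariates(toy_cells(), toy_sites())
        # site-level constants: mean of (-0.5, 0.9), sample sd over the 2 sites
        assert std.center["z_cwd"] == pytest.approx(0.2)
        assert std.scale["z_cwd"] == pytest.approx(np.std([-0.5, 0.9], ddof=1))
        assert tab.groupby("site_id")["z_cwd"].nunique().max() == 1

    def test_interaction_columns_not_recentered(self):
        tab, _ = standardize_covariates(toy_cells(), toy_sites())
        prod = (tab["z_cwd"] * tab["z_host_height"]).to_numpy()
        np.testing.assert_allclose(tab["z_cwd:z_host_height"].to_numpy(), prod)
        # generally nonzero mean, by construction
        assert abs(tab["z_cwd:z_host_height"].mean()) > 1e-6

    def test_hostless_cells_excluded(self):
        cells = toy_cells()
        cells.loc[1, "n_host"] = 0
        tab, _ = standardize_covariates(cells, toy_sites())
        assert len(tab) == 3

    def test_zero_variance_covariate_fails_by_name(self):
        cells = toy_cells()
        cells["total_ba_m2"] = 1.0
        with pytest.raises(ValueError, match="total_ba_m2"):
            standardize_covariates(cells, toy_sites())

    def test_missing_site_reported(self):
        with pytest.raises(ValueError, match="sites missing"):
            standardize_covariates(toy_cells(), toy_sites().iloc[:1])


class TestSubsample:
    def test_small_site_returned_whole(self):
        cells = toy_cells()
        out = subsample_cells(cells, k=200, seed=0)
        assert len(out) == len(cells)

    def test_seed_determinism_and_uniqueness(self):
        cells = pd.DataFrame(
            {"site_id": "s", "cell_ix": np.arange(1000), "v": np.arange(1000)}
        )
        a = subsample_cells(cells, k=200, seed=5)
        b = subsample_cells(cells, k=200, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 200
        assert a["cell_ix"].is_unique

    def test_per_site_cap(self):
        cells = pd.DataFrame(
            {"site_id": ["a"] * 50 + ["b"] * 10, "cell_ix": np.arange(60)}
        )
        out = subsample_cells(cells, k=20, seed=1)
        sizes = out.groupby("site_id").size()
        assert sizes["a"] == 20 and sizes["b"] == 10

    def test_bad_k(self):
        with pytest.raises(ValueError):
            subsample_cells(toy_cells(), k=0)
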