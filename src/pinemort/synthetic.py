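"""Synthetic landscapes, stem maps, canopy rasters and crown spectra.

Everything downstream of the drone-image pipeline can be exercised against
data generated here with known ground truth:

* :func:`generate_landscape` is the generative inverse of the mortality
  model -- sites along a climatic-water-deficit (CWD) gradient, ~200 20-m
  grid cells per site with host/density/height/basal-area covariates, a
  spatially autocorrelated per-site Gaussian-process field drawn exactly
  (dense covariance + Cholesky), and zero-inflated binomial dead counts.
* :func:`generate_stem_map` draws individual-tree tables from a homogeneous
  Poisson process (fixtures for detection validation).
* :func:`render_chm` rasterizes a stem map into a canopy height model by
  max-compositing paraboloid crowns.
* :func:`render_crown_spectra` draws five-band crown reflectance means
  around live ("green vegetation") and dead ("dry/gray") templates.

All generators are pure functions of (config, seed): the same inputs give
bit-identical outputs. Per-site random substreams are derived from the root
seed by fixed offsets so one site can be regenerated without the others.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .design import design_matrix
from .gridding import RAW_FOR_Z, Standardization, interaction_columns
from .model.gp import JITTER, safe_cholesky, squared_distances
from .model.likelihood import zib_rvs
from .raster import Raster

__all__ = [
    "SyntheticConfig",
    "StemMapSpec",
    "SiteData",
    "Landscape",
    "generate_landscape",
    "generate_stem_map",
    "render_chm",
    "render_crown_spectra",
    "LIVE_TEMPLATE",
    "DEAD_TEMPLATE",
]

#: mortality-model coefficients used by default; the effect sizes mirror the
#: posterior medians of the study system (strong positive CWD, host
#: proportion and host-height effects; a strong CWD x height interaction).
DEFAULT_BETA = (
    -1.0,   # b0 intercept
    0.85,   # b1 cwd
    0.68,   # b2 prop host
    0.25,   # b3 mean host height
    -0.01,  # b4 overall density
    -0.13,  # b5 overall basal area
    0.54,   # b6 cwd : height
    -0.08,  # b7 cwd : prop host
    -0.19,  # b8 cwd : density
    -0.04,  # b9 cwd : ba
    0.0,    # b10 prop host : height
    0.06,   # b11 prop host : density
    -0.08,  # b12 height : ba
    0.14,   # b13 cwd : prop host : height
)

CELL_M = 20.0


@dataclass
class SyntheticConfig:
    """Controls for the landscape generator.

    Defaults describe the study conditions: 32 sites spanning a CWD z-score
    gradient, a 15 x 15 block of 20-m cells per site (225 cells, of which
    ``cells_per_site`` are kept), cell covariates bracketing the field-plot
    means (~20 trees and ~18 m mean host height per cell), and a per-site
    GP with half-cell-scale spatial correlation of the mortality log-odds.
    """

    n_sites: int = 32
    cells_per_site: int = 225
    grid_side_cells: int = 15
    cwd_range: tuple[float, float] = (-1.5, 1.5)
    beta: tuple[float, ...] = DEFAULT_BETA
    zi_p: float = 0.08
    gp_sd: float = 0.5            # log-odds units
    gp_lengthscale: float = 40.0  # metres
    # covariate distributions
    host_prop_beta: tuple[float, float] = (2.0, 2.0)
    density_mean: float = 20.0    # trees per cell
    density_dispersion: float = 5.0
    height_lognorm: tuple[float, float] = (np.log(18.0), 0.3)  # (mu, sigma) of log m
    dbh_per_height: float = 2.5   # cm DBH per m height, for per-tree basal area
    ba_lognoise_sd: float = 0.25  # within-cell height-spread noise on cell BA
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.cells_per_site < 1:
            raise ValueError("n_sites and cells_per_site must be >= 1")
        if self.cells_per_site > self.grid_side_cells**2:
            raise ValueError("cells_per_site exceeds the site grid capacity")
        if not 0.0 <= self.zi_p <= 1.0:
            raise ValueError("zi_p must be in [0, 1]")
        if self.gp_sd < 0 or self.gp_lengthscale <= 0:
            raise ValueError("gp_sd must be >= 0 and gp_lengthscale > 0")
        if self.cwd_range[0] > self.cwd_range[1]:
            raise ValueError("cwd_range must be ordered")
        if len(self.beta) != 14:
            raise ValueError("beta must have 14 entries (b0..b13)")

    def to_yaml(self, path: str | Path) -> None:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, float)):
                return float(v)
            if isinstance(v, (np.integer, int)):
                return int(v)
            return v

        d = {k: plain(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("cwd_range", "beta", "host_prop_beta", "height_lognorm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SiteData:
    """One site: identifier, CWD z-score, and its cell table with latents."""

    site_id: str
    cwd_z: float
    cells: pd.DataFrame  # includes true_pi, gp_value, eligible


@dataclass
class Landscape:
    sites: list[SiteData]
    config: SyntheticConfig
    standardization: Standardization

    @property
    def cells(self) -> pd.DataFrame:
        """All cells pooled across sites (raw + standardized + latents)."""
        return pd.concat([s.cells for s in self.sites], ignore_index=True)

    @property
    def sites_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": [s.site_id for s in self.sites],
             "cwd_z": [s.cwd_z for s in self.sites]}
        )

    def model_table(self) -> pd.DataFrame:
        """Eligible cells only, ready for the model (design columns present)."""
        return self.cells.loc[lambda d: d["eligible"]].reset_index(drop=True)

    def write_csv(self, outdir: str | Path) -> None:
        """Write the cell table, the site table and the config (YAML)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cells.csv", index=False)
        self.sites_table.to_csv(outdir / "sites.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def _site_rngs(seed: int, n_sites: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n_sites)]


def generate_landscape(config: SyntheticConfig) -> Landscape:
    """Simulate the full multi-site landscape with known true mortality.

    Per site: cell covariates are drawn from the configured distributions,
    the GP field is drawn exactly over cell centroids, the linear predictor
    is assembled from standardized covariates (pooled standardization, CWD
    over sites), and dead counts follow the zero-inflated binomial. All
    latent quantities (true pi, GP draw) are kept in the cell table.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0FFEE)))
    site_rngs = _site_rngs(config.seed, config.n_sites)
    cwd = np.sort(rng.uniform(*config.cwd_range, size=config.n_sites))

    side = config.grid_side_cells
    nb_n = config.density_dispersion
    nb_p = nb_n / (nb_n + config.density_mean)

    site_frames = []
    for j in range(config.n_sites):
        srng = site_rngs[j]
        n_cells = config.cells_per_site
        chosen = np.sort(srng.choice(side * side, size=n_cells, replace=False))
        ix, iy = np.divmod(chosen, side)
        cx = (ix + 0.5) * CELL_M
        cy = (iy + 0.5) * CELL_M

        prop = srng.beta(*config.host_prop_beta, size=n_cells)
        n_total = srng.negative_binomial(nb_n, nb_p, size=n_cells)
        mean_h = srng.lognormal(*config.height_lognorm, size=n_cells)
        n_host = np.round(n_total * prop).astype(int)
        dbh_cm = config.dbh_per_height * mean_h
        per_tree_ba = np.pi * (dbh_cm / 200.0) ** 2
        ba = (
            n_total
            * per_tree_ba
            * np.exp(srng.normal(0.0, config.ba_lognoise_sd, size=n_cells))
        )

        site_frames.append(
            pd.DataFrame(
                {
                    "site_id": f"site{j:02d}",
                    "cell_ix": ix,
                    "cell_iy": iy,
                    "centroid_x_m": cx,
                    "centroid_y_m": cy,
                    "n_total": n_total,
                    "n_host": n_host,
                    "prop_host": np.where(n_total > 0, n_host / np.maximum(n_total, 1), np.nan),
                    "mean_host_height_m": np.where(n_host > 0, mean_h, np.nan),
                    "total_ba_m2": ba,
                    "cwd_z_raw": cwd[j],
                    "eligible": n_host > 0,
                }
            )
        )

    cells = pd.concat(site_frames, ignore_index=True)

    # pooled standardization over eligible cells; CWD constants over sites
    standardization = Standardization()
    elig = cells["eligible"].to_numpy()
    for zname, raw in RAW_FOR_Z.items():
        vals = cwd if zname == "z_cwd" else cells.loc[elig, raw].to_numpy(dtype=float)
        standardization.center[zname] = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if not sd > 0:
            raise ValueError(f"degenerate synthetic covariate {raw!r} (zero variance)")
        standardization.scale[zname] = sd
    for zname, raw in RAW_FOR_Z.items():
        z = standardization.transform(zname, cells[raw].to_numpy(dtype=float))
        cells[zname] = np.where(np.isnan(z) & ~elig, 0.0, z)  # ineligible: placeholder
    cells = interaction_columns(cells)

    beta = np.asarray(config.beta, dtype=float)
    eta = design_matrix(cells) @ beta

    # exact per-site GP draw over cell centroids
    gp_all = np.zeros(len(cells))
    for j in range(config.n_sites):
        mask = (cells["site_id"] == f"site{j:02d}").to_numpy()
        if config.gp_sd > 0:
            coords = cells.loc[mask, ["centroid_x_m", "centroid_y_m"]].to_numpy()
            R = np.exp(-0.5 * squared_distances(coords) / config.gp_lengthscale**2)
            L = safe_cholesky(R + JITTER * np.eye(mask.sum()), label=f"site{j:02d}")
            gp_all[mask] = config.gp_sd * (L @ site_rngs[j].standard_normal(mask.sum()))
    eta = eta + gp_all

    pi = special.expit(eta)
    y = zib_rvs(cells["n_host"].to_numpy(), pi, config.zi_p, rng)
    cells["gp_value"] = gp_all
    cells["true_pi"] = np.where(elig, pi, np.nan)
    cells["y_dead"] = np.where(elig, y, 0)

    sites = [
        SiteData(
            site_id=f"site{j:02d}",
            cwd_z=float(cwd[j]),
            cells=cells.loc[cells["site_id"] == f"site{j:02d}"].reset_index(drop=True),
        )
        for j in range(config.n_sites)
    ]
    return Landscape(sites=sites, config=config, standardization=standardization)


# -- individual-tree fixtures ----------------------------------------------


@dataclass
class StemMapSpec:
    """A homogeneous-Poisson stem map on a rectangular extent."""

    extent_m: tuple[float, float] = (100.0, 100.0)  # (width, height)
    density: float = 400.0  # trees per hectare
    height_lognorm: tuple[float, float] = (np.log(18.0), 0.35)
    host_fraction: float = 0.7
    dead_fraction: float = 0.25
    crown_radius_per_height: float = 0.08  # m crown radius per m height
    crown_radius_intercept: float = 0.5    # m
    seed: int = 0

    def __post_init__(self):
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("stem-map extent must have positive area")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        for frac in (self.host_fraction, self.dead_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


NON_HOST_SPECIES = ("ABCO", "CADE", "PILA", "QUKE")


def generate_stem_map(spec: StemMapSpec) -> pd.DataFrame:
    """Tree table: positions, heights, species/host, live/dead, crown radii."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.extent_m
    area_ha = w * h / 1e4
    n = rng.poisson(spec.density * area_ha)
    height = rng.lognormal(*spec.height_lognorm, size=n)
    host = rng.random(n) < spec.host_fraction
    dead = rng.random(n) < spec.dead_fraction
    species = np.where(host, "PIPO", rng.choice(NON_HOST_SPECIES, size=n))
    crown = np.maximum(
        0.5, spec.crown_radius_intercept + spec.crown_radius_per_height * height
    )
    return pd.DataFrame(
        {
            "tree_id": np.arange(n),
            "x_m": rng.uniform(0.0, w, size=n),
            "y_m": rng.uniform(0.0, h, size=n),
            "height_m": height,
            "species": species,
            "host": host.astype(int),
            "dead": dead.astype(int),
            "crown_radius_m": crown,
        }
    )


def render_chm(
    trees: pd.DataFrame,
    resolution_m: float = 0.5,
    extent_m: tuple[float, float] | None = None,
) -> Raster:
    """Rasterize a stem map into a canopy height model.

    Each tree contributes a paraboloid crown surface
    ``z(r) = h * (1 - (r / R)^2)`` truncated at its crown radius ``R``; the
    raster takes the maximum over contributing crowns and 0 where none
    reach. The apex pixel therefore equals the tree height to within one
    resolution step.
    """
    if resolution_m <= 0:
        raise ValueError("resolution must be > 0")
    if extent_m is None:
        if trees.empty:
            extent_m = (resolution_m, resolution_m)
        else:
            pad = float(trees["crown_radius_m"].max())
            extent_m = (
                float(trees["x_m"].max()) + pad,
                float(trees["y_m"].max()) + pad,
            )
    ncol = max(1, int(np.ceil(extent_m[0] / resolution_m)))
    nrow = max(1, int(np.ceil(extent_m[1] / resolution_m)))
    canvas = np.zeros((nrow, ncol))
    raster = Raster(values=canvas, resolution=resolution_m)
    xs = raster.x_coords()
    ys = raster.y_coords()

    for tree in trees.itertuples():
        R = tree.crown_radius_m
        c0 = np.searchsorted(xs, tree.x_m - R)
        c1 = np.searchsorted(xs, tree.x_m + R, side="right")
        rows = np.where(np.abs(ys - tree.y_m) <= R)[0]
        if c1 <= c0 or rows.size == 0:
            continue
        dx = xs[c0:c1] - tree.x_m
        dy = ys[rows] - tree.y_m
        r2 = dy[:, None] ** 2 + dx[None, :] ** 2
        z = tree.height_m * (1.0 - r2 / R**2)
        block = canvas[np.ix_(rows, np.arange(c0, c1))]
        canvas[np.ix_(rows, np.arange(c0, c1))] = np.maximum(block, np.clip(z, 0, None))
        # the stem pixel carries the full tree height (the paraboloid is
        # evaluated at the pixel center, a hair off the apex)
        col = int(np.clip(tree.x_m // resolution_m, 0, ncol - 1))
        row = int(np.clip(nrow - 1 - tree.y_m // resolution_m, 0, nrow - 1))
        canvas[row, col] = max(canvas[row, col], tree.height_m)
    return raster


# -- crown reflectance fixtures --------------------------------------------

BANDS = ("blue", "green", "red", "red_edge", "nir")

#: surface-reflectance templates: healthy foliage has a strong red edge
#: (high NIR, low red); dry gray/brown crowns lose NIR and gain red.
LIVE_TEMPLATE = {"blue": 0.04, "green": 0.08, "red": 0.05, "red_edge": 0.20, "nir": 0.45}
DEAD_TEMPLATE = {"blue": 0.08, "green": 0.12, "red": 0.16, "red_edge": 0.20, "nir": 0.24}

#: small species-level shifts (applied on top of the live/dead template)
SPECIES_OFFSETS = {
    "PIPO": {"green": 0.000, "nir": 0.000},
    "ABCO": {"green": 0.010, "nir": -0.020},
    "CADE": {"green": -0.008, "nir": 0.025},
    "PILA": {"green": 0.005, "nir": 0.015},
    "QUKE": {"green": 0.015, "nir": -0.035},
}


def render_crown_spectra(trees: pd.DataFrame, noise_sd: float = 0.01,
                         seed: int = 0) -> pd.DataFrame:
    """Per-crown five-band reflectance means for a labelled tree table.

    Live crowns are drawn around the green-vegetation template, dead crowns
    around the dry/gray template, with species offsets, iid Gaussian noise
    of ``noise_sd`` per band, and clipping to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(trees)
    dead = trees["dead"].to_numpy(dtype=bool)
    species = trees["species"].to_numpy()
    out = {"crown_id": trees["tree_id"].to_numpy() if "tree_id" in trees else np.arange(n)}
    for band in BANDS:
        base = np.where(dead, DEAD_TEMPLATE[band], LIVE_TEMPLATE[band])
        offsets = np.array([SPECIES_OFFSETS.get(sp, {}).get(band, 0.0) for sp in species])
        vals = base + offsets + rng.normal(0.0, noise_sd, size=n)
        out[band] = np.clip(vals, 0.0, 1.0)
    df = pd.DataFrame(out)
    for col in ("species", "host", "dead"):
        if col in trees:
            df[col] = trees[col].to_numpy()
    return df
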