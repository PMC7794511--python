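"""Aggregation of classified tree tables to 20 x 20-m grid cells.

This is the final data-preparation stage before modelling: trees (with
live/dead status, host flag, calibrated height and basal area) are binned
into square cells, per-cell covariates are computed under the
"dead-trees-are-hosts" convention, covariates are centered and scaled, and
cells are subsampled per site to limit spatial redundancy.

Conventions
-----------
* Cells are half-open: a tree at exactly ``origin + cell_m`` falls in cell 1.
* A dead tree counts as a host (the study system's dead trees are taken to
  be ponderosa pine): ``n_host = live hosts + all dead``, and the mean host
  height averages that same set. Pass ``dead_is_host=False`` for the
  live-only alternative.
* Cells with no host trees have an undefined mean host height and are
  flagged ineligible for the model table rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BASE_COVARIATES, interaction_columns

logger = logging.getLogger(__name__)

__all__ = [
    "Standardization",
    "rasterize_trees",
    "standardize_covariates",
    "subsample_cells",
]

#: raw cell-table column for each standardized covariate
RAW_FOR_Z = {
    "z_cwd": "cwd_z_raw",
    "z_prop_host": "prop_host",
    "z_host_height": "mean_host_height_m",
    "z_density": "n_total",
    "z_ba": "total_ba_m2",
}


@dataclass
class Standardization:
    """Center/scale constants (mean, sample sd) for the five base covariates."""

    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center[name]) / self.scale[name]

    def inverse(self, name: str, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale[name] + self.center[name]


def rasterize_trees(
    trees: pd.DataFrame,
    origin: tuple[float, float] | str = "auto",
    cell_m: float = 20.0,
    shape: tuple[int, int] | None = None,
    dead_is_host: bool = True,
) -> pd.DataFrame:
    """Bin a classified tree table into grid cells.

    Parameters
    ----------
    trees
        Columns ``x_m, y_m, host, dead, height_m`` and optionally ``ba_m2``
        (missing basal area contributes 0) and ``site_id``.
    origin
        ``(x0, y0)`` of the grid, or ``"auto"``: the floor of the minimum
        tree coordinates to a ``cell_m`` multiple.
    shape
        Optional ``(nx, ny)`` cell counts. Trees falling outside are dropped
        with a logged count. Without it the grid covers all trees, and every
        cell of the bounding rectangle is emitted (zero-count cells included).

    Returns
    -------
    DataFrame with one row per cell: ``cell_ix, cell_iy, centroid_x_m,
    centroid_y_m, y_dead, n_host, n_total, mean_host_height_m, total_ba_m2,
    prop_host, eligible`` (plus ``site_id`` if present in the input).
    """
    trees = trees.reset_index(drop=True)
    if trees.empty and shape is None:
        raise ValueError("cannot infer grid extent from an empty tree table")

    if origin == "auto":
        x0 = np.floor(trees["x_m"].min() / cell_m) * cell_m
        y0 = np.floor(trees["y_m"].min() / cell_m) * cell_m
    else:
        x0, y0 = origin  # type: ignore[misc]

    ix = np.floor((trees["x_m"].to_numpy() - x0) / cell_m).astype(int)
    iy = np.floor((trees["y_m"].to_numpy() - y0) / cell_m).astype(int)

    if shape is not None:
        nx, ny = shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        n_dropped = int((~inside).sum())
        if n_dropped:
            logger.warning("rasterize_trees: dropped %d trees outside the grid extent", n_dropped)
        trees, ix, iy = trees[inside], ix[inside], iy[inside]
    else:
        n_dropped = 0
        if len(trees):
            nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
        else:
            nx = ny = 0

    dead = trees["dead"].to_numpy(dtype=bool)
    host = trees["host"].to_numpy(dtype=bool)
    height = trees["height_m"].to_numpy(dtype=float)
    ba = trees["ba_m2"].to_numpy(dtype=float) if "ba_m2" in trees else np.zeros(len(trees))
    # dead trees are treated as hosts for trials, heights and proportions
    is_host_eff = (host & ~dead) | dead if dead_is_host else host

    flat = ix * ny + iy if ny else np.array([], dtype=int)
    n_cells = nx * ny
    n_total = np.bincount(flat, minlength=n_cells)
    y_dead = np.bincount(flat[dead], minlength=n_cells)
    n_host = np.bincount(flat[is_host_eff], minlength=n_cells)
    h_sum = np.bincount(flat[is_host_eff], weights=height[is_host_eff], minlength=n_cells)
    ba_sum = np.bincount(flat, weights=ba, minlength=n_cells)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = np.where(n_host > 0, h_sum / np.maximum(n_host, 1), np.nan)
        prop_host = np.where(n_total > 0, n_host / np.maximum(n_total, 1), np.nan)

    cix, ciy = np.divmod(np.arange(n_cells), ny) if ny else (np.array([], int),) * 2
    out = pd.DataFrame(
        {
            "cell_ix": cix,
            "cell_iy": ciy,
            "centroid_x_m": x0 + (cix + 0.5) * cell_m,
            "centroid_y_m": y0 + (ciy + 0.5) * cell_m,
            "y_dead": y_dead,
            "n_host": n_host,
            "n_total": n_total,
            "mean_host_height_m": mean_h,
            "total_ba_m2": ba_sum,
            "prop_host": prop_host,
            "eligible": n_host > 0,
        }
    )
    if "site_id" in trees.columns and len(trees):
        out.insert(0, "site_id", trees["site_id"].iloc[0])
    out.attrs["n_dropped"] = n_dropped
    out.attrs["origin"] = (float(x0), float(y0))
    out.attrs["cell_m"] = float(cell_m)
    return out


def standardize_covariates(
    cells: pd.DataFrame,
    sites: pd.DataFrame,
    standardization: Standardization | None = None,
) -> tuple[pd.DataFrame, Standardization]:
    """Build the standardized model table from a cell table plus site CWD.

    Cells with ``n_host == 0`` are excluded first (their mean host height is
    undefined). Each base covariate is centered and scaled by its mean and
    sample sd pooled over the included cells, except CWD whose constants come
    from the *site-level* values and are replicated to cells. Interaction
    columns are products of standardized base columns, not re-centered.

    Parameters
    ----------
    cells
        Output of :func:`rasterize_trees` (pooled over sites), with ``site_id``.
    sites
        Columns ``site_id, cwd_z`` (site climatic-water-deficit z-score).
    standardization
        Reuse existing constants (e.g. to standardize held-out cells);
        computed from the data when None.

    Returns
    -------
    (model_table, Standardization) -- model table has ``y_dead``/``n_host``,
    raw covariates, the five z-columns and eight interaction columns.
    """
    tab = cells.loc[cells["n_host"] > 0].copy()
    if tab.empty:
        raise ValueError("no cells with at least one host tree")
    site_cwd = sites.set_index("site_id")["cwd_z"]
    tab["cwd_z_raw"] = tab["site_id"].map(site_cwd).astype(float)
    if tab["cwd_z_raw"].isna().any():
        missing = sorted(set(tab.loc[tab["cwd_z_raw"].isna(), "site_id"]))
        raise ValueError(f"sites missing from the site table: {missing}")

    if standardization is None:
        standardization = Standardization()
        for zname, raw in RAW_FOR_Z.items():
            if zname == "z_cwd":
                vals = site_cwd.loc[sorted(set(tab["site_id"]))].to_numpy(dtype=float)
            else:
                vals = tab[raw].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            if not sd > 0:
                raise ValueError(f"covariate {raw!r} has zero variance; cannot standardize")
            standardization.center[zname] = float(np.mean(vals))
            standardization.scale[zname] = sd

    for zname, raw in RAW_FOR_Z.items():
        tab[zname] = standardization.transform(zname, tab[raw].to_numpy())

    tab = interaction_columns(tab)
    assert all(c in tab.columns for c in BASE_COVARIATES)
    return tab.reset_index(drop=True), standardization


def subsample_cells(
    cells: pd.DataFrame,
    k: int = 200,
    seed: int | np.random.Generator = 0,
    by_site: bool = True,
) -> pd.DataFrame:
    """Uniform random subsample of up to ``k`` cells (per site when grouped).

    Sites with at most ``k`` cells are returned whole. Deterministic for a
    given seed; sampling is without replacement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def take(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) <= k:
            return group
        idx = rng.choice(len(group), size=k, replace=False)
        return group.iloc[np.sort(idx)]

    if by_site and "site_id" in cells.columns:
        parts = [take(g) for _, g in cells.groupby("site_id", sort=True)]
        return pd.concat(parts).reset_index(drop=True)
    return take(cells).reset_index(drop=True)
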