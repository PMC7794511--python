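"""Tree-detection benchmarking against ground plots.

A reference local-maxima detector stands in for the detection algorithms
under test; candidates (algorithm x parameter set) are compared to ground
data at the *plot-summary* level -- the seven structure metrics, never
tree-by-tree matching -- using Pearson correlation, RMSE and the median of
(air - ground) so that positive means the aerial workflow overestimates.

The winner is picked by the 5%-of-best tally rule: per metric a candidate
scores if its correlation is within 5% of the best correlation or its RMSE
within 5% of the best (lowest) RMSE; the candidate reaching the thresholds
on the most metrics wins. ``both_criteria=True`` requires correlation and
RMSE together before a metric counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Raster
from .structure import METRIC_NAMES

__all__ = ["EvalResult", "reference_detector", "evaluate_detection", "select_best"]


@dataclass
class EvalResult:
    """Per-candidate benchmark: one row of statistics per structure metric."""

    algorithm_id: str
    parameter_set: dict[str, Any] = field(default_factory=dict)
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # filled by select_best:
    within5_r: dict[str, bool] = field(default_factory=dict)
    within5_rmse: dict[str, bool] = field(default_factory=dict)
    tally: int = 0


def reference_detector(
    chm: Raster, window_m: float, min_height_m: float = 2.0
) -> pd.DataFrame:
    """Fixed-window local-maxima treetop detector on a canopy height model.

    A pixel is a detection iff its value is at least ``min_height_m`` and is
    the strict maximum within the square window centred on it; exact ties
    within a window keep only the first pixel in row-major order. Returns
    pixel-center coordinates and CHM heights.
    """
    if min_height_m < 0:
        raise ValueError("min_height_m must be >= 0")
    half = int(round(window_m / (2.0 * chm.resolution)))
    if half < 1:
        raise ValueError("window must span at least the raster resolution")
    v = np.asarray(chm.values, dtype=float)
    nrow, ncol = v.shape
    xs, ys = chm.x_coords(), chm.y_coords()

    from scipy.ndimage import maximum_filter

    size = 2 * half + 1
    is_max = (v == maximum_filter(v, size=size, mode="constant", cval=-np.inf)) & (
        v >= min_height_m
    )
    rows, cols = np.nonzero(is_max)
    keep = np.ones(len(rows), dtype=bool)
    # resolve plateaus/ties: row-major first occurrence within the window wins
    for k in range(len(rows)):
        r, c = rows[k], cols[k]
        r0, c0 = max(0, r - half), max(0, c - half)
        block = v[r0 : r + half + 1, c0 : c + half + 1]
        tie_r, tie_c = np.nonzero(block == v[r, c])
        tie_r, tie_c = tie_r + r0, tie_c + c0
        first = np.lexsort((tie_c, tie_r))[0]
        if (tie_r[first], tie_c[first]) != (r, c):
            keep[k] = False
    rows, cols = rows[keep], cols[keep]
    return pd.DataFrame(
        {"x_m": xs[cols], "y_m": ys[rows], "height_m": v[rows, cols]}
    )


def evaluate_detection(
    air_metrics: pd.DataFrame,
    ground_metrics: pd.DataFrame,
    algorithm_id: str = "candidate",
    parameter_set: dict[str, Any] | None = None,
) -> EvalResult:
    """Per-metric Pearson r, RMSE and median (air - ground) over plots.

    Both tables are indexed by plot_id with the seven metric columns. A
    metric with zero variance in either vector gets an undefined (NaN)
    correlation, which later drops it from the correlation criterion.
    """
    if not air_metrics.index.equals(ground_metrics.index):
        air_metrics = air_metrics.loc[ground_metrics.index]
    if len(ground_metrics) < 3:
        raise ValueError("need at least 3 plots for a correlation")
    rows = []
    for m in METRIC_NAMES:
        air = air_metrics[m].to_numpy(dtype=float)
        ground = ground_metrics[m].to_numpy(dtype=float)
        ok = ~(np.isnan(air) | np.isnan(ground))
        air, ground = air[ok], ground[ok]
        diff = air - ground
        if len(air) >= 3 and np.std(air) > 0 and np.std(ground) > 0:
            r = float(stats.pearsonr(air, ground).statistic)
        else:
            r = np.nan
        rows.append(
            {
                "metric": m,
                "pearson_r": r,
                "rmse": float(np.sqrt(np.mean(diff**2))) if len(diff) else np.nan,
                "median_error": float(np.median(diff)) if len(diff) else np.nan,
                "n_plots": int(len(air)),
            }
        )
    return EvalResult(
        algorithm_id=algorithm_id,
        parameter_set=parameter_set or {},
        stats=pd.DataFrame(rows).set_index("metric"),
    )


def select_best(results: list[EvalResult], both_criteria: bool = False) -> EvalResult:
    """Apply the 5%-of-best tally rule and return the winner.

    Per metric, a candidate is marked if ``r >= 0.95 * max r`` (skipped for
    metrics whose best correlation is <= 0, where a multiplicative band is
    meaningless) and if ``rmse <= 1.05 * min rmse``. The tally counts
    metrics reaching either threshold (or both, with ``both_criteria``).
    Ties in the tally break by higher mean correlation, then input order.
    """
    if not results:
        raise ValueError("select_best needs at least one candidate")
    metrics = list(results[0].stats.index)

    best_r = {
        m: np.nanmax([res.stats.loc[m, "pearson_r"] for res in results]) for m in metrics
    }
    best_rmse = {
        m: np.nanmin([res.stats.loc[m, "rmse"] for res in results]) for m in metrics
    }

    for res in results:
        tally = 0
        for m in metrics:
            r = res.stats.loc[m, "pearson_r"]
            rmse = res.stats.loc[m, "rmse"]
            hit_r = (
                bool(np.isfinite(r) and np.isfinite(best_r[m]) and best_r[m] > 0
                     and r >= 0.95 * best_r[m])
            )
            hit_rmse = bool(np.isfinite(rmse) and rmse <= 1.05 * best_rmse[m])
            res.within5_r[m] = hit_r
            res.within5_rmse[m] = hit_rmse
            if (hit_r and hit_rmse) if both_criteria else (hit_r or hit_rmse):
                tally += 1
        res.tally = tally

    def sort_key(item):
        i, res = item
        mean_r = np.nanmean(res.stats["pearson_r"].to_numpy(dtype=float))
        return (-res.tally, -(mean_r if np.isfinite(mean_r) else -np.inf), i)

    return sorted(enumerate(results), key=sort_key)[0][1]
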