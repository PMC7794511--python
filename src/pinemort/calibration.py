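"""Height calibration, height-to-DBH allometry, basal area, CWD z-scores.

Drone-measured (photogrammetric) tree heights are biased: needleless dead
treetops are under-reconstructed, while field methods tend to overestimate
live tree heights. The calibration fits ordinary least squares of field
height on drone height separately for live and dead trees, using only
pairs where the drone height exceeds a fitting threshold (default 20 m),
and applies the resulting linear correction to *all* trees of that status.

Basal area comes from species-specific linear height-to-DBH allometries fit
on field trees, and site climatic water deficit (CWD, mm) is expressed as a
z-score against a reference distribution (the host species' climatic range,
e.g. a herbarium-record sample): z = +1 means one standard deviation
hotter/drier than the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeightCalibration",
    "Allometry",
    "CwdReference",
    "fit_height_calibration",
    "apply_height_calibration",
    "fit_allometry",
    "predict_dbh",
    "basal_area",
    "cwd_zscore",
]

FIELD_DBH_MIN_CM = 6.35  # field inclusion rule for allometry fits


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of y on x; raises on a singular (constant-x) fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x - x.mean()
    sxx = float(sx @ sx)
    if sxx <= 1e-12 * max(1.0, float(x @ x)):
        raise ValueError("singular fit: predictor has no variance")
    slope = float(sx @ (y - y.mean())) / sxx
    return slope, float(y.mean() - slope * x.mean())


@dataclass
class HeightCalibration:
    status: str           # "live" or "dead"
    slope: float
    intercept: float      # m
    fit_threshold_m: float
    n_pairs: int

    def correct(self, drone_height_m):
        """Corrected height, floored at 0 (applies to all trees, not only
        those above the fitting threshold)."""
        h = self.slope * np.asarray(drone_height_m, dtype=float) + self.intercept
        return np.maximum(h, 0.0)

    def inverse(self, field_height_m):
        if self.slope == 0:
            raise ValueError("calibration is not invertible (zero slope)")
        return (np.asarray(field_height_m, dtype=float) - self.intercept) / self.slope


def fit_height_calibration(
    pairs: pd.DataFrame, fit_threshold_m: float = 20.0
) -> dict[str, HeightCalibration]:
    """Per-status OLS of field height on drone height.

    ``pairs`` columns: ``drone_height_m, field_height_m, status`` with
    status in {live, dead}. Only pairs with drone height strictly above
    ``fit_threshold_m`` enter the fit.
    """
    out: dict[str, HeightCalibration] = {}
    for status, grp in pairs.groupby("status"):
        sel = grp.loc[grp["drone_height_m"] > fit_threshold_m]
        if len(sel) < 2:
            raise ValueError(
                f"need >= 2 pairs above {fit_threshold_m} m for status {status!r}, "
                f"got {len(sel)}"
            )
        slope, intercept = _ols(
            sel["drone_height_m"].to_numpy(), sel["field_height_m"].to_numpy()
        )
        out[status] = HeightCalibration(
            status=status, slope=slope, intercept=intercept,
            fit_threshold_m=fit_threshold_m, n_pairs=len(sel),
        )
    return out


def apply_height_calibration(
    trees: pd.DataFrame,
    calibrations: dict[str, HeightCalibration],
    height_col: str = "height_m",
) -> pd.DataFrame:
    """Replace drone heights with status-specific corrected heights."""
    statuses = np.where(trees["dead"].to_numpy(dtype=bool), "dead", "live")
    missing = sorted(set(statuses) - set(calibrations))
    if missing:
        raise ValueError(f"no calibration for status(es): {missing}")
    out = trees.copy()
    h = out[height_col].to_numpy(dtype=float)
    corrected = np.empty_like(h)
    for status, cal in calibrations.items():
        mask = statuses == status
        corrected[mask] = cal.correct(h[mask])
    out[height_col] = corrected
    return out


@dataclass
class Allometry:
    """Linear height-to-DBH relation for one species (and optional status)."""

    species: str
    slope: float       # cm DBH per m height
    intercept: float   # cm
    r2: float
    n_trees: int

    def predict_dbh_cm(self, height_m):
        return np.maximum(self.slope * np.asarray(height_m, dtype=float) + self.intercept, 0.0)


def fit_allometry(
    field_trees: pd.DataFrame, min_trees: int = 3, dbh_min_cm: float = FIELD_DBH_MIN_CM
) -> dict[str, Allometry]:
    """Per-species OLS of DBH (cm) on height (m) from field-measured trees.

    Trees at or below the field DBH inclusion threshold are dropped.
    Species with fewer than ``min_trees`` remaining are skipped with a
    warning rather than fitted.
    """
    import warnings

    out: dict[str, Allometry] = {}
    trees = field_trees.loc[field_trees["dbh_cm"] > dbh_min_cm]
    for species, grp in trees.groupby("species"):
        if len(grp) < min_trees:
            warnings.warn(
                f"species {species!r}: only {len(grp)} usable trees (<{min_trees}); skipped"
            )
            continue
        h = grp["height_m"].to_numpy(dtype=float)
        d = grp["dbh_cm"].to_numpy(dtype=float)
        slope, intercept = _ols(h, d)
        resid = d - (slope * h + intercept)
        tot = float(np.sum((d - d.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tot if tot > 0 else np.nan
        out[species] = Allometry(species, slope, intercept, r2, len(grp))
    return out


def predict_dbh(
    trees: pd.DataFrame, allometries: dict[str, Allometry], dead_species: str = "PIPO"
) -> pd.DataFrame:
    """Attach allometric DBH and basal area to a classified tree table.

    Dead trees use the host-species allometry regardless of their species
    label (dead trees are assumed to be ponderosa pine).
    """
    out = trees.copy()
    species = out["species"].astype(str).to_numpy()
    if "dead" in out:
        species = np.where(out["dead"].to_numpy(dtype=bool), dead_species, species)
    dbh = np.empty(len(out))
    for sp in np.unique(species):
        if sp not in allometries:
            raise ValueError(f"no allometry for species {sp!r}")
        mask = species == sp
        dbh[mask] = allometries[sp].predict_dbh_cm(out.loc[mask, "height_m"].to_numpy())
    out["dbh_cm"] = dbh
    out["ba_m2"] = basal_area(dbh)
    return out


def basal_area(dbh_cm):
    """Cross-sectional stem area in m^2: pi * (DBH/2)^2 with DBH in metres."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm < 0):
        raise ValueError("DBH must be >= 0")
    out = np.pi * (dbh_cm / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class CwdReference:
    """Reference CWD sample (mm) defining the z-score frame."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("reference needs at least 2 values")
        if not self.sd > 0:
            raise ValueError("reference CWD values have zero variance")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def cwd_zscore(site_cwd_mm, reference: CwdReference):
    """Site CWD as standard deviations from the reference mean (+1 = one sd
    hotter/drier than the reference distribution's mean)."""
    z = (np.asarray(site_cwd_mm, dtype=float) - reference.mean) / reference.sd
    return float(z) if z.ndim == 0 else z
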