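"""Vegetation indices, crown-mean feature extraction, and the
cross-validated classification harness for live/dead and host/non-host.

Feature design follows the ten-variable scheme: the five band means per
crown plus the five indices *computed from those band means* (not averages
of per-pixel index maps; ``per_pixel_indices=True`` switches to the
pixel-then-average reading). The classifier is pluggable -- anything with
``fit(X, y)`` and ``predict(X)`` -- with L2-regularized logistic regression
as the default.
"""

from __future__ import annotations

from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .raster import Raster

__all__ = [
    "BAND_NAMES",
    "INDEX_NAMES",
    "FEATURE_COLUMNS",
    "compute_indices",
    "extract_crown_features",
    "crossval_classify",
]

BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")
INDEX_NAMES = ("ndvi", "ndre", "rgi", "ci_rededge", "ci_green")
FEATURE_COLUMNS = BAND_NAMES + INDEX_NAMES


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    return np.where(den == 0, np.nan, out)


def compute_indices(bands: Mapping[str, Any] | pd.DataFrame) -> pd.DataFrame | pd.Series:
    """Five vegetation indices from five band reflectances.

    NDVI = (NIR - R)/(NIR + R); NDRE = (NIR - RE)/(NIR + RE); RGI = R/G;
    CI_rededge = NIR/RE - 1; CI_green = NIR/G - 1. A zero denominator gives
    NaN for that crown, never +/-inf. Accepts a mapping of scalars or a
    DataFrame with the band columns.
    """
    scalar = not isinstance(bands, pd.DataFrame)
    b = {k: np.atleast_1d(np.asarray(bands[k], dtype=float)) for k in BAND_NAMES}
    if any(np.any((v < 0) | (v > 1)) for v in b.values()):
        raise ValueError("band reflectances must lie in [0, 1]")
    out = pd.DataFrame(
        {
            "ndvi": _safe_div(b["nir"] - b["red"], b["nir"] + b["red"]),
            "ndre": _safe_div(b["nir"] - b["red_edge"], b["nir"] + b["red_edge"]),
            "rgi": _safe_div(b["red"], b["green"]),
            "ci_rededge": _safe_div(b["nir"], b["red_edge"]) - 1.0,
            "ci_green": _safe_div(b["nir"], b["green"]) - 1.0,
        }
    )
    return out.iloc[0] if scalar else out


def extract_crown_features(
    rasters: Mapping[str, Raster],
    crowns: Sequence,
    crown_ids: Sequence | None = None,
    per_pixel_indices: bool = False,
) -> pd.DataFrame:
    """Crown-mean band values plus indices for each crown geometry.

    Parameters
    ----------
    rasters
        One co-registered :class:`~pinemort.raster.Raster` per band name.
    crowns
        Shapely polygons, or ``(x, y, radius)`` triples for circular crowns.
        A pixel belongs to a crown iff its *center* falls inside the
        geometry (boundary inclusive). Crowns capturing no pixel centers get
        all-NaN features and ``n_pixels = 0``.
    per_pixel_indices
        Average per-pixel index values instead of deriving indices from the
        band means.
    """
    missing = [b for b in BAND_NAMES if b not in rasters]
    if missing:
        raise ValueError(f"missing bands: {missing}")
    ref = rasters[BAND_NAMES[0]]
    xs, ys = ref.pixel_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    band_flat = {b: np.asarray(rasters[b].values, dtype=float).ravel() for b in BAND_NAMES}
    for b in BAND_NAMES:
        if rasters[b].values.shape != ref.values.shape:
            raise ValueError("band rasters are not co-registered (shape mismatch)")

    geoms = [
        g if hasattr(g, "geom_type") else Point(g[0], g[1]).buffer(g[2], quad_segs=64)
        for g in crowns
    ]
    ids = list(crown_ids) if crown_ids is not None else list(range(len(geoms)))

    rows = []
    for cid, geom in zip(ids, geoms):
        minx, miny, maxx, maxy = geom.bounds
        near = (
            (flat_x >= minx) & (flat_x <= maxx) & (flat_y >= miny) & (flat_y <= maxy)
        )
        idx = np.nonzero(near)[0]
        if idx.size:
            inside = shapely.covers(geom, shapely.points(flat_x[idx], flat_y[idx]))
            idx = idx[inside]
        row: dict[str, Any] = {"crown_id": cid, "n_pixels": int(idx.size)}
        if idx.size == 0:
            row.update({c: np.nan for c in FEATURE_COLUMNS})
        else:
            means = {b: float(np.mean(band_flat[b][idx])) for b in BAND_NAMES}
            row.update(means)
            if per_pixel_indices:
                per_pix = compute_indices(
                    pd.DataFrame({b: band_flat[b][idx] for b in BAND_NAMES})
                )
                row.update(per_pix.mean().to_dict())
            else:
                row.update(compute_indices(means).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def crossval_classify(
    features: pd.DataFrame,
    labels: Sequence,
    k: int = 5,
    classifier: Any | None = None,
    seed: int = 0,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> dict[str, Any]:
    """Stratified k-fold cross-validated classification.

    Returns overall held-out accuracy, per-fold accuracies and confusion
    matrices, and the held-out prediction per crown. Any object with
    ``fit``/``predict`` can replace the default regularized logistic
    regression (the study's boosted logistic regression and regularized
    discriminant analysis both satisfy this contract).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratification failure: class {classes[counts.argmin()]!r} has "
            f"{counts.min()} members, fewer than k={k}"
        )
    X = features[list(feature_columns)].to_numpy(dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("features contain NaN; drop flagged crowns first")
    if classifier is None:
        classifier = LogisticRegression(max_iter=2000, C=1.0)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    fold_acc, fold_cm = [], []
    for train, test in skf.split(X, y):
        import copy

        clf = copy.deepcopy(classifier)
        clf.fit(X[train], y[train])
        p = np.asarray(clf.predict(X[test]))
        pred[test] = p
        fold_acc.append(float(np.mean(p == y[test])))
        fold_cm.append(confusion_matrix(y[test], p, labels=classes))
    return {
        "accuracy": float(np.mean(pred == y)),
        "fold_accuracies": fold_acc,
        "fold_confusion": fold_cm,
        "classes": classes,
        "predictions": pred,
    }
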