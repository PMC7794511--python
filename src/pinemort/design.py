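"""Fixed-effects design for the mortality model.

The linear predictor for the log-odds of host mortality in a 20-m cell uses
five standardized base covariates -- site climatic water deficit (CWD)
z-score, proportion of trees that are hosts, mean host height, overall tree
density, overall basal area -- plus seven two-way interactions and one
three-way interaction, in a fixed order shared by the simulator, the
gridding stage, and the model:

    b0
    b1  cwd          b2  prop_host    b3  host_height
    b4  density      b5  ba
    b6  cwd:height   b7  cwd:prop_host
    b8  cwd:density  b9  cwd:ba
    b10 prop_host:height   b11 prop_host:density
    b12 height:ba
    b13 cwd:prop_host:height

Interaction columns are products of the standardized base columns and are
deliberately *not* re-centered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASE_COVARIATES = ["z_cwd", "z_prop_host", "z_host_height", "z_density", "z_ba"]

#: design column names in coefficient order b1..b13 (b0 is the intercept)
DESIGN_COLUMNS = [
    "z_cwd",
    "z_prop_host",
    "z_host_height",
    "z_density",
    "z_ba",
    "z_cwd:z_host_height",
    "z_cwd:z_prop_host",
    "z_cwd:z_density",
    "z_cwd:z_ba",
    "z_prop_host:z_host_height",
    "z_prop_host:z_density",
    "z_host_height:z_ba",
    "z_cwd:z_prop_host:z_host_height",
]

N_BETA = len(DESIGN_COLUMNS) + 1  # 14: intercept + 13 slopes

COEFFICIENT_NAMES = ["b0_intercept"] + [
    f"b{i + 1}_{name}" for i, name in enumerate(DESIGN_COLUMNS)
]


def interaction_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append the 8 interaction columns to a table of standardized covariates.

    ``table`` must contain the five BASE_COVARIATES columns.
    """
    out = table.copy()
    out["z_cwd:z_host_height"] = out["z_cwd"] * out["z_host_height"]
    out["z_cwd:z_prop_host"] = out["z_cwd"] * out["z_prop_host"]
    out["z_cwd:z_density"] = out["z_cwd"] * out["z_density"]
    out["z_cwd:z_ba"] = out["z_cwd"] * out["z_ba"]
    out["z_prop_host:z_host_height"] = out["z_prop_host"] * out["z_host_height"]
    out["z_prop_host:z_density"] = out["z_prop_host"] * out["z_density"]
    out["z_host_height:z_ba"] = out["z_host_height"] * out["z_ba"]
    out["z_cwd:z_prop_host:z_host_height"] = (
        out["z_cwd"] * out["z_prop_host"] * out["z_host_height"]
    )
    return out


def design_matrix(table: pd.DataFrame, intercept: bool = True) -> np.ndarray:
    """Design matrix in coefficient order; first column all-ones if requested."""
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"model table lacks design columns: {missing}")
    X = table[DESIGN_COLUMNS].to_numpy(dtype=float)
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X
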