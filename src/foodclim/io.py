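"""CSV (and optional NetCDF) readers/writers with schema validation.

All CSV dialects: UTF-8, comma-separated, mandatory header row, years as
integers, prevalences on the 0–100 scale.  Validation errors report
1-based file line numbers (header is line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table violates its schema; the message carries the line number."""


def _line(df: pd.DataFrame, mask) -> int:
    """1-based CSV line number of the first offending row."""
    return int(df.index[mask][0]) + 2


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns {missing}")


def _float_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


# -- climate ---------------------------------------------------------------

CLIMATE_COLS = ["region_id", "year", "month", "tmean_c", "precip_mm"]


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CLIMATE_COLS, "climate")
    for col in ("year", "month"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise SchemaError(f"climate column {col!r} must be integer")
    bad = ~df["month"].between(1, 12)
    if bad.any():
        raise SchemaError(f"invalid calendar month at line {_line(df, bad)}")
    bad = df["precip_mm"] < 0
    if bad.any():
        raise SchemaError(f"negative precipitation at line {_line(df, bad)}")
    return df


def write_climate(df: pd.DataFrame, path) -> None:
    _float_csv(df[CLIMATE_COLS], path)


# -- survey responses ------------------------------------------------------

RESPONSE_COLS = ["region_id", "year", "weight"] + [f"q{i}" for i in range(1, 9)]


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RESPONSE_COLS, "responses")
    bad = ~(df["weight"] > 0)
    if bad.any():
        raise SchemaError(f"non-positive survey weight at line {_line(df, bad)}")
    for i in range(1, 9):
        col = df[f"q{i}"]
        bad = ~(col.isin([0, 1]) | col.isna())
        if bad.any():
            raise SchemaError(f"non-binary answer in q{i} at line {_line(df, bad)}")
    return df


def write_responses(df: pd.DataFrame, path) -> None:
    _float_csv(df[RESPONSE_COLS], path)


# -- region-year panel -----------------------------------------------------

PANEL_REQUIRED = ["region_id", "year"]


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PANEL_REQUIRED, "panel")
    if df.duplicated(["region_id", "year"]).any():
        line = _line(df, df.duplicated(["region_id", "year"]))
        raise SchemaError(f"duplicated (region_id, year) key at line {line}")
    for col in ("msfi", "sfi", "msfi_true", "sfi_true"):
        if col in df.columns:
            bad = ~df[col].between(0, 100) & df[col].notna()
            if bad.any():
                raise SchemaError(f"prevalence {col!r} outside [0, 100] at line {_line(df, bad)}")
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    _float_csv(df, path)


# -- scenarios and groups --------------------------------------------------

def read_scenarios(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["region_id", "year", "anomaly_factual", "anomaly_counterfactual"], "scenario")
    return df


def read_group_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["region_id", "group"], "group map")
    if df["region_id"].duplicated().any():
        raise SchemaError(
            f"region mapped twice at line {_line(df, df['region_id'].duplicated())}"
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    _float_csv(df, path)


# -- optional gridded input ------------------------------------------------

def read_gridded(path):
    """Open a NetCDF (CF-style) temperature/precipitation grid."""
    import xarray as xr

    try:
        return xr.open_dataset(path)
    except Exception:
        return xr.open_dataset(path, engine="scipy")


def read_region_masks(path, shape: tuple[int, ...]) -> dict[str, np.ndarray]:
    """Region weight masks from CSV (region_id, cell_index, weight).

    ``cell_index`` indexes the row-major flattened spatial grid of ``shape``.
    """
    df = pd.read_csv(path)
    _require(df, ["region_id", "cell_index", "weight"], "mask")
    bad = df["weight"] < 0
    if bad.any():
        raise SchemaError(f"negative mask weight at line {_line(df, bad)}")
    ncell = int(np.prod(shape))
    bad = ~df["cell_index"].between(0, ncell - 1)
    if bad.any():
        raise SchemaError(f"cell index outside grid at line {_line(df, bad)}")
    masks: dict[str, np.ndarray] = {}
    for region, grp in df.groupby("region_id"):
        w = np.zeros(ncell)
        w[grp["cell_index"].to_numpy(int)] = grp["weight"].to_numpy(float)
        masks[str(region)] = w.reshape(shape)
    return masks
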