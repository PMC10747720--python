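"""Tabular input/output and validation for the monitoring data model.

All stages exchange plain pandas DataFrames with fixed column contracts
(comma-separated UTF-8 files on disk, header row mandatory):

``trees``
    one stem-circumference measurement per tree and year —
    ``plot_id, tree_id, species, year, circumference_cm``
``plots``
    per-plot site covariates (topography, soil chemistry/texture, richness)
``climate_grid``
    gridded annual climate per grid point and year —
    ``point_id, lon, lat, elevation_m, year, temp_ann_c, precip_ann_mm,
    precip_jja_mm``

Validation rejects malformed rows (duplicate tree-years, non-positive
circumference, unknown species codes) with a logged warning rather than
failing the whole file; a missing column is a hard error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Species codes used throughout: FS = Fagus sylvatica (common beech),
#: PA = Picea abies (Norway spruce), AA = Abies alba (silver fir),
#: QP = Quercus petraea (sessile oak), PS = Pinus sylvestris (Scots pine).
SPECIES_CODES = ("FS", "PA", "AA", "QP", "PS")

TREE_COLUMNS = ["plot_id", "tree_id", "species", "year", "circumference_cm"]

PLOT_COLUMNS = [
    "plot_id", "lon", "lat", "elevation_m", "aspect_deg", "slope_deg",
    "tree_richness", "pH_H2O", "clay_pct", "silt_pct", "sand_pct",
    "total_N", "organic_C", "c_n_ratio",
]

CLIMATE_GRID_COLUMNS = [
    "point_id", "lon", "lat", "elevation_m", "year",
    "temp_ann_c", "precip_ann_mm", "precip_jja_mm",
]

#: Published summary of the Slovak ICP Forests Level I tree-growth monitoring
#: network (1988–2023) that the synthetic generator emulates: national species
#: proportion (%, national forest inventory), plots, measured individuals and
#: annual increment records per species.
MONITORING_SUMMARY = pd.DataFrame(
    {
        "species": ["FS", "PA", "QP", "PS", "AA"],
        "proportion_pct": [30.1, 18.7, 7.2, 4.8, 2.8],
        "n_plots": [67, 55, 34, 27, 19],
        "n_individuals": [2251, 2236, 651, 643, 351],
        "n_records": [53255, 43438, 14703, 14117, 7485],
    }
).set_index("species")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def validate_trees(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a circumference table, dropping invalid rows with a warning.

    Enforces: positive circumference, known species codes, at most one record
    per (plot_id, tree_id, year). Returns a clean copy; rejects are logged.
    """
    _require_columns(df, TREE_COLUMNS, "trees table")
    out = df[TREE_COLUMNS].copy()
    out["year"] = out["year"].astype(int)
    out["circumference_cm"] = out["circumference_cm"].astype(float)

    bad_circ = ~(out["circumference_cm"] > 0)
    if bad_circ.any():
        logger.warning("rejected %d rows with non-positive circumference",
                       int(bad_circ.sum()))
        out = out[~bad_circ]

    bad_sp = ~out["species"].isin(SPECIES_CODES)
    if bad_sp.any():
        logger.warning("rejected %d rows with unknown species codes %s",
                       int(bad_sp.sum()),
                       sorted(out.loc[bad_sp, "species"].unique()))
        out = out[~bad_sp]

    dup = out.duplicated(subset=["plot_id", "tree_id", "year"], keep="first")
    if dup.any():
        logger.warning("rejected %d duplicate (plot, tree, year) rows",
                       int(dup.sum()))
        out = out[~dup]

    return out.reset_index(drop=True)


def validate_plots(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the plot-environment table.

    Soil texture fractions must sum to 100 within rounding tolerance and the
    C:N ratio must equal organic_C/total_N where both are present; missing
    soil values are permitted and propagated.
    """
    _require_columns(df, PLOT_COLUMNS, "plots table")
    out = df[PLOT_COLUMNS].copy()
    tex = out[["clay_pct", "silt_pct", "sand_pct"]].sum(axis=1, skipna=False)
    bad_tex = tex.notna() & ((tex < 99) | (tex > 101))
    if bad_tex.any():
        raise ValueError(
            f"soil texture fractions do not sum to ~100 for plots "
            f"{out.loc[bad_tex, 'plot_id'].tolist()}"
        )
    both = out["organic_C"].notna() & out["total_N"].notna() & out["c_n_ratio"].notna()
    expect = out.loc[both, "organic_C"] / out.loc[both, "total_N"]
    off = ~np.isclose(out.loc[both, "c_n_ratio"], expect, rtol=1e-6)
    if off.any():
        raise ValueError(
            f"c_n_ratio inconsistent with organic_C/total_N for plots "
            f"{out.loc[both].loc[off, 'plot_id'].tolist()}"
        )
    return out.reset_index(drop=True)


def validate_climate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the gridded-climate table: non-negative precipitation and
    identical year coverage at every grid point."""
    _require_columns(df, CLIMATE_GRID_COLUMNS, "climate grid table")
    out = df[CLIMATE_GRID_COLUMNS].copy()
    out["year"] = out["year"].astype(int)
    if (out[["precip_ann_mm", "precip_jja_mm"]] < 0).any().any():
        raise ValueError("negative precipitation in climate grid")
    cover = out.groupby("point_id")["year"].agg(frozenset)
    if cover.nunique() > 1:
        raise ValueError("climate grid points differ in year coverage")
    return out.reset_index(drop=True)


def read_circumference_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a ``trees.csv`` circumference table."""
    return validate_trees(pd.read_csv(path))


def read_plot_table(path: str | Path) -> pd.DataFrame:
    return validate_plots(pd.read_csv(path))


def read_climate_grid(path: str | Path) -> pd.DataFrame:
    return validate_climate_grid(pd.read_csv(path))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any stage table as CSV with full float precision (round-trip safe).

    An empty frame yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path
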