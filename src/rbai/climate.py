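"""Plot-level climate from a gridded product, and drought pointer years.

Interpolation: for each plot, the 4 nearest grid points (great-circle
distance) are each first corrected from grid-point elevation to plot
elevation with fixed vertical lapse rates — temperature −0.7 °C per +100 m,
precipitation +40 mm per +100 m on the annual total, the JJA (June–August)
total receiving the annual correction scaled by its share of the annual
total — and then combined by inverse-distance weights. A plot coincident
with a grid point receives that point's corrected value exactly.

Dry (pointer) years: a year is flagged dry when its JJA precipitation total
falls below the plot's long-term normal (arithmetic mean over the normal
period, default 1950–2021) at *strictly more than* a threshold fraction
(default 90%) of the monitoring plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
LAPSE_TEMP_C_PER_100M = 0.7
LAPSE_PRECIP_MM_PER_100M = 40.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class DryYearReport:
    """Per-year fraction of plots below their JJA normal, and the flagged set."""
    fractions: pd.DataFrame  # columns: year, fraction_below_normal
    dry_years: list[int]
    threshold: float = 0.90
    normal_period: tuple[int, int] = (1950, 2021)


def interpolate_to_plot(
    grid: pd.DataFrame,
    plot: pd.Series | dict,
    n_neighbors: int = 4,
    lapse_temp: float = LAPSE_TEMP_C_PER_100M,
    lapse_precip: float = LAPSE_PRECIP_MM_PER_100M,
    max_distance_km: float | None = None,
) -> pd.DataFrame:
    """Interpolate a climate grid to one plot.

    Returns a per-year DataFrame ``plot_id, year, temp_ann_c, precip_ann_mm,
    precip_jja_mm``. Precipitation corrected below zero is floored at 0 with
    a warning.
    """
    points = grid[["point_id", "lon", "lat", "elevation_m"]].drop_duplicates("point_id")
    if len(points) < n_neighbors:
        raise ValueError(f"need at least {n_neighbors} grid points")
    d = haversine_km(plot["lon"], plot["lat"],
                     points["lon"].to_numpy(), points["lat"].to_numpy())
    order = np.argsort(d, kind="stable")[:n_neighbors]
    near = points.iloc[order].copy()
    near["dist_km"] = d[order]
    if max_distance_km is not None and near["dist_km"].min() > max_distance_km:
        logger.warning("plot %s is %.1f km from the nearest grid point",
                       plot["plot_id"], near["dist_km"].min())

    dz100 = (plot["elevation_m"] - near["elevation_m"].to_numpy()) / 100.0

    sub = grid[grid["point_id"].isin(near["point_id"])]
    wide_t = sub.pivot(index="year", columns="point_id", values="temp_ann_c")
    wide_p = sub.pivot(index="year", columns="point_id", values="precip_ann_mm")
    wide_j = sub.pivot(index="year", columns="point_id", values="precip_jja_mm")
    ids = near["point_id"].to_numpy()
    wide_t, wide_p, wide_j = wide_t[ids], wide_p[ids], wide_j[ids]

    t_adj = wide_t.to_numpy() - lapse_temp * dz100
    dp = lapse_precip * dz100
    p_raw = wide_p.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        jja_share = np.where(p_raw > 0, wide_j.to_numpy() / p_raw, 0.0)
    p_adj = p_raw + dp
    j_adj = wide_j.to_numpy() + dp * jja_share
    if (p_adj < 0).any() or (j_adj < 0).any():
        logger.warning("plot %s: lapse correction drove precipitation below 0; floored",
                       plot["plot_id"])
        p_adj = np.clip(p_adj, 0.0, None)
        j_adj = np.clip(j_adj, 0.0, None)

    dist = near["dist_km"].to_numpy()
    if (dist == 0).any():
        w = (dist == 0).astype(float)  # coincident point wins exactly
    else:
        w = 1.0 / dist
    w = w / w.sum()

    return pd.DataFrame(
        {
            "plot_id": plot["plot_id"],
            "year": wide_t.index.to_numpy(),
            "temp_ann_c": t_adj @ w,
            "precip_ann_mm": p_adj @ w,
            "precip_jja_mm": j_adj @ w,
        }
    )


def interpolate_all_plots(grid: pd.DataFrame, plots: pd.DataFrame, **kw) -> pd.DataFrame:
    """Interpolate the grid to every plot; concatenated long table."""
    return pd.concat(
        [interpolate_to_plot(grid, row, **kw) for _, row in plots.iterrows()],
        ignore_index=True,
    )


def jja_normal(series: pd.DataFrame, normal_period: tuple[int, int] = (1950, 2021)) -> float:
    """Arithmetic-mean JJA precipitation total over the normal period (mm)."""
    y0, y1 = normal_period
    wanted = set(range(y0, y1 + 1))
    have = set(series["year"].astype(int))
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(f"normal period years missing from series: {missing}")
    mask = series["year"].between(y0, y1)
    return float(series.loc[mask, "precip_jja_mm"].mean())


def detect_dry_years(
    plot_series: pd.DataFrame,
    normal_period: tuple[int, int] = (1950, 2021),
    threshold: float = 0.90,
    study_years: tuple[int, int] | None = None,
) -> DryYearReport:
    """Flag years whose JJA total is below normal at > threshold of plots.

    ``plot_series`` is the long table from :func:`interpolate_all_plots`.
    The inequality on the fraction is strict: exactly 90% of plots below
    normal does not flag the year.
    """
    normals = plot_series.groupby("plot_id", sort=False).apply(
        lambda s: jja_normal(s, normal_period), include_groups=False
    )
    df = plot_series.merge(normals.rename("jja_normal_mm"), on="plot_id")
    df["below"] = df["precip_jja_mm"] < df["jja_normal_mm"]
    frac = (
        df.groupby("year")["below"].mean().rename("fraction_below_normal").reset_index()
    )
    if study_years is not None:
        frac = frac[frac["year"].between(*study_years)].reset_index(drop=True)
    dry = sorted(frac.loc[frac["fraction_below_normal"] > threshold, "year"].astype(int))
    return DryYearReport(fractions=frac, dry_years=dry,
                         threshold=threshold, normal_period=tuple(normal_period))
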