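"""Synthetic ICP-Forests-Level-I-like data with known ground truth.

The generator emulates the structure of a national tree-growth monitoring
network in the Western Carpathians: ~115 permanent plots on a regular grid,
five species (FS, PA, AA, QP, PS) with unequal plot occupancy, 36 years of
annual stem-circumference records per tree, per-plot site covariates, and a
0.1° gridded climate product with elevation-dependent temperature and
precipitation.

Growth is generated on the RBAI scale and converted to circumference through
the basal-area recursion ``BA_t = BA_{t−1} / (1 − RBAI_t/100)`` — the same
direction the analysis reads it. The expected RBAI of species *s* in year
*t* is linear in time,

    E[RBAI_st] = baseline_s + trend_s · (t − t0),

multiplied in injected drought years by a plot-specific factor
``drought_multiplier · q_p`` where the plot response ``q_p`` is coupled to
standardized elevation with configurable correlation (higher plots suffer
less, mimicking an elevation-moderated drought signal). Individual noise is
multiplicative lognormal with unit mean, so circumference series are
strictly increasing and every stage's expected output is known analytically
from the emitted ground-truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import SPECIES_CODES

#: the drought pointer years injected by default (synchronous JJA deficits)
DEFAULT_DROUGHT_YEARS = (1990, 1992, 1993, 1994, 2000, 2003,
                         2012, 2013, 2015, 2017, 2019, 2022)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_plots: int = 115
    n_trees_per_plot_per_species: int = 4
    #: proportions over (FS, PA, AA, QP, PS); drives per-plot occupancy
    species_mix: tuple = (0.37, 0.36, 0.06, 0.11, 0.10)
    #: expected number of species per plot (occupancy_s = mix_s * richness)
    plot_richness_target: float = 1.8
    years: tuple = (1988, 2023)
    #: %/yr linear change in expected RBAI per species
    true_rbai_trend_per_species: dict = field(default_factory=lambda: {
        "FS": -0.029, "PA": -0.008, "AA": 0.0, "QP": -0.012, "PS": -0.020,
    })
    #: expected RBAI (%) in the first increment year
    baseline_rbai_per_species: dict = field(default_factory=lambda: {
        "FS": 3.0, "PA": 1.8, "AA": 2.5, "QP": 2.2, "PS": 1.5,
    })
    drought_years: tuple = DEFAULT_DROUGHT_YEARS
    #: multiplicative dip of expected RBAI in drought years, (0, 1]
    drought_multiplier: float = 0.6
    #: lognormal (meanlog, sdlog) of initial circumference, cm, clipped ≥ min
    size_init: tuple = (4.1, 0.4)
    size_min_cm: float = 15.0
    elevation_range_m: tuple = (200.0, 1400.0)
    lapse_temp_c_per_100m: float = 0.7
    lapse_precip_mm_per_100m: float = 40.0
    #: sd of the multiplicative lognormal growth noise per tree-year
    noise_sd: float = 0.15
    #: sd of a lognormal growth factor shared by all trees of a plot in a
    #: year (site-level weather/stand effects decorrelating dry-year columns)
    site_year_sd: float = 0.30
    #: correlation between elevation and the plot drought-response factor q_p
    elevation_response_r: float = 0.5
    #: spread of q_p around 1 (relative)
    response_sd: float = 0.15
    #: sd of lognormal spatial jitter on JJA totals (0 = no spatial field)
    climate_spatial_sd: float = 0.25
    #: shared JJA factor range in drought years (fraction of climatology)
    drought_jja_factor: tuple = (0.45, 0.70)
    #: shared JJA factor range in non-drought years; bounded away from the
    #: long-term normal so only injected deficits are network-synchronous
    normal_jja_factor: tuple = (1.05, 1.40)
    climate_years: tuple = (1950, 2023)
    grid_spacing_deg: float = 0.1
    lon_range: tuple = (17.0, 22.0)
    lat_range: tuple = (48.3, 49.6)
    seed: int = 20231206

    def validate(self) -> None:
        if abs(sum(self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species_mix must sum to 1")
        if not (0.0 < self.drought_multiplier <= 1.0):
            raise ValueError("drought_multiplier must be in (0, 1]")
        y0, y1 = self.years
        for s in SPECIES_CODES:
            b = self.baseline_rbai_per_species[s]
            tr = self.true_rbai_trend_per_species[s]
            worst = min(b, b + tr * (y1 - (y0 + 1)))
            if worst * self.drought_multiplier <= 0:
                raise ValueError(
                    f"expected RBAI for {s} becomes non-positive within the "
                    f"simulated period (worst {worst:.3g}%)"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def _rngs(cfg: SimulationConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(cfg.seed)
    plots_ss, trees_ss, climate_ss = root.spawn(3)
    return {
        "plots": np.random.default_rng(plots_ss),
        "trees": np.random.default_rng(trees_ss),
        "climate": np.random.default_rng(climate_ss),
    }


def _terrain(lon, lat, cfg: SimulationConfig):
    """Smooth deterministic elevation surface spanning elevation_range_m."""
    lo, hi = cfg.elevation_range_m
    u = (lon - cfg.lon_range[0]) / max(cfg.lon_range[1] - cfg.lon_range[0], 1e-9)
    v = (lat - cfg.lat_range[0]) / max(cfg.lat_range[1] - cfg.lat_range[0], 1e-9)
    s = 0.5 + 0.25 * np.sin(2 * np.pi * u * 1.7) + 0.25 * np.cos(2 * np.pi * v * 1.3)
    return lo + (hi - lo) * s


def simulate_plot_environments(cfg: SimulationConfig, rng=None):
    """Plot table plus per-plot ground truth (elevation z-score, response q).

    Soil texture triplets are drawn on the simplex (sum exactly 100 up to
    float rounding); C:N ratio is organic_C/total_N by construction. The
    drought-response factor ``q_p`` is built with population correlation
    ``elevation_response_r`` to standardized elevation.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["plots"]
    n = cfg.n_plots
    lon = rng.uniform(*cfg.lon_range, n)
    lat = rng.uniform(*cfg.lat_range, n)
    elev = _terrain(lon, lat, cfg) + rng.normal(0, 0.02 * np.ptp(cfg.elevation_range_m) + 1e-9, n)
    z = (elev - elev.mean()) / (elev.std() if elev.std() > 0 else 1.0)

    r = cfg.elevation_response_r
    eps = rng.normal(size=n)
    q = 1.0 + cfg.response_sd * (r * z + np.sqrt(max(1 - r * r, 0.0)) * eps)
    q = np.clip(q, 0.05, None)

    texture = rng.dirichlet((2.0, 3.0, 3.0), size=n) * 100.0
    total_N = np.exp(rng.normal(np.log(0.25), 0.4, n))
    cn = np.exp(rng.normal(np.log(15.0), 0.25, n))
    organic_C = total_N * cn

    plots = pd.DataFrame({
        "plot_id": [f"P{i:03d}" for i in range(n)],
        "lon": lon, "lat": lat, "elevation_m": elev,
        "aspect_deg": rng.uniform(0, 360, n),
        "slope_deg": rng.exponential(6.0, n),
        "tree_richness": 1 + rng.poisson(2.0, n),
        "pH_H2O": np.clip(rng.normal(5.3, 0.9, n), 3.5, 8.0),
        "clay_pct": texture[:, 0], "silt_pct": texture[:, 1], "sand_pct": texture[:, 2],
        "total_N": total_N, "organic_C": organic_C,
        "c_n_ratio": organic_C / total_N,
    })
    truth = pd.DataFrame({
        "plot_id": plots["plot_id"], "elev_z": z, "response_q": q,
        "dry_multiplier": np.clip(cfg.drought_multiplier * q, None, 1.0),
    })
    return plots, truth


def expected_rbai_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Species×year ground-truth expectations (at mean-elevation response q=1)."""
    y0, y1 = cfg.years
    years = np.arange(y0 + 1, y1 + 1)  # increment years
    rows = []
    for s in SPECIES_CODES:
        base = (cfg.baseline_rbai_per_species[s]
                + cfg.true_rbai_trend_per_species[s] * (years - (y0 + 1)))
        dry = np.isin(years, list(cfg.drought_years))
        rows.append(pd.DataFrame({
            "species": s, "year": years, "base_rbai_pct": base,
            "is_drought": dry,
            "expected_rbai_pct": np.where(dry, base * cfg.drought_multiplier, base),
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_trees(cfg: SimulationConfig, plot_truth: pd.DataFrame, rng=None):
    """Circumference records for every simulated tree, plus the truth tables.

    Returns ``(trees, truth_species_year)``; per-plot truth comes from
    :func:`simulate_plot_environments`.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["trees"]
    y0, y1 = cfg.years
    inc_years = np.arange(y0 + 1, y1 + 1)
    n_inc = len(inc_years)

    occupancy = np.clip(np.asarray(cfg.species_mix) * cfg.plot_richness_target, 0, 1)
    plot_ids = plot_truth["plot_id"].to_numpy()
    dry_mult = plot_truth["dry_multiplier"].to_numpy()

    # draw species presence per plot; guarantee ≥1 species everywhere
    present = rng.random((len(plot_ids), len(SPECIES_CODES))) < occupancy
    empty = ~present.any(axis=1)
    if empty.any():
        forced = rng.integers(0, len(SPECIES_CODES), size=int(empty.sum()))
        present[np.where(empty)[0], forced] = True

    tree_plot, tree_species = [], []
    for i, pid in enumerate(plot_ids):
        for j, s in enumerate(SPECIES_CODES):
            if present[i, j]:
                tree_plot.extend([i] * cfg.n_trees_per_plot_per_species)
                tree_species.extend([j] * cfg.n_trees_per_plot_per_species)
    tree_plot = np.asarray(tree_plot)
    tree_species = np.asarray(tree_species)
    n_trees = len(tree_plot)

    truth_sy = expected_rbai_table(cfg)
    base = np.empty((len(SPECIES_CODES), n_inc))
    for j, s in enumerate(SPECIES_CODES):
        sub = truth_sy[truth_sy["species"] == s].sort_values("year")
        base[j] = sub["base_rbai_pct"].to_numpy()
    dry_mask = np.isin(inc_years, list(cfg.drought_years))

    expect = base[tree_species]  # (n_trees, n_inc)
    mult = np.where(dry_mask[None, :], dry_mult[tree_plot][:, None], 1.0)
    expect = expect * mult

    ssd = cfg.site_year_sd
    site = (np.exp(ssd * rng.normal(size=(len(plot_ids), n_inc)) - 0.5 * ssd * ssd)
            if ssd > 0 else np.ones((len(plot_ids), n_inc)))
    eps = rng.normal(size=(n_trees, n_inc))
    sd = cfg.noise_sd
    realized = expect * site[tree_plot] * np.exp(sd * eps - 0.5 * sd * sd)
    if (realized >= 100).any():
        raise RuntimeError("realized RBAI reached 100%; reduce noise_sd")

    c0 = np.maximum(np.exp(rng.normal(cfg.size_init[0], cfg.size_init[1], n_trees)),
                    cfg.size_min_cm)
    ba0 = c0 * c0 / (4 * np.pi)
    growth = 1.0 / (1.0 - realized / 100.0)
    ba = ba0[:, None] * np.cumprod(growth, axis=1)
    circ = np.sqrt(4 * np.pi * ba)

    all_years = np.concatenate([[y0], inc_years])
    all_circ = np.concatenate([c0[:, None], circ], axis=1)
    trees = pd.DataFrame({
        "plot_id": np.repeat(plot_ids[tree_plot], len(all_years)),
        "tree_id": np.repeat([f"T{i:05d}" for i in range(n_trees)], len(all_years)),
        "species": np.repeat(np.asarray(SPECIES_CODES)[tree_species], len(all_years)),
        "year": np.tile(all_years, n_trees),
        "circumference_cm": all_circ.ravel(),
    })
    return trees, truth_sy


def simulate_climate_grid(cfg: SimulationConfig, rng=None):
    """Gridded annual climate, 1950–2023, with injected JJA drought deficits.

    Temperature follows the configured lapse rate exactly (−0.7 °C/100 m off
    a smooth terrain); annual precipitation gains 40 mm/100 m. JJA totals are
    a point climatology times a shared per-year factor — markedly below 1 in
    drought years, at-or-above 1 otherwise — times lognormal spatial jitter
    of sd ``climate_spatial_sd`` (0 turns the spatial field off entirely).

    Returns ``(grid, truth)`` where truth carries the per-year shared factor.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["climate"]
    lons = np.arange(cfg.lon_range[0], cfg.lon_range[1] + 1e-9, cfg.grid_spacing_deg)
    lats = np.arange(cfg.lat_range[0], cfg.lat_range[1] + 1e-9, cfg.grid_spacing_deg)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    elev = _terrain(glon, glat, cfg)
    n_pts = len(glon)

    years = np.arange(cfg.climate_years[0], cfg.climate_years[1] + 1)
    n_y = len(years)
    dry = np.isin(years, list(cfg.drought_years))

    shared = np.where(
        dry,
        rng.uniform(*cfg.drought_jja_factor, n_y),
        rng.uniform(*cfg.normal_jja_factor, n_y),
    )
    temp_anom = rng.normal(0, 0.4, n_y)

    sd = cfg.climate_spatial_sd
    jitter = (np.exp(rng.normal(0, sd, (n_pts, n_y)) - 0.5 * sd * sd)
              if sd > 0 else np.ones((n_pts, n_y)))
    t_noise = rng.normal(0, 0.3, (n_pts, n_y)) if sd > 0 else 0.0

    temp = (9.5 - cfg.lapse_temp_c_per_100m * elev[:, None] / 100.0
            + temp_anom[None, :] + t_noise)
    base_ann = 520.0 + cfg.lapse_precip_mm_per_100m * elev / 100.0
    jja_clim = 0.35 * base_ann
    jja = jja_clim[:, None] * shared[None, :] * jitter
    rest = 0.65 * base_ann[:, None] * (np.exp(rng.normal(0, 0.05, (n_pts, n_y)))
                                       if sd > 0 else 1.0)
    precip = rest + jja

    grid = pd.DataFrame({
        "point_id": np.repeat([f"G{i:04d}" for i in range(n_pts)], n_y),
        "lon": np.repeat(glon, n_y),
        "lat": np.repeat(glat, n_y),
        "elevation_m": np.repeat(elev, n_y),
        "year": np.tile(years, n_pts),
        "temp_ann_c": temp.ravel(),
        "precip_ann_mm": precip.ravel(),
        "precip_jja_mm": jja.ravel(),
    })
    truth = pd.DataFrame({
        "year": years, "jja_shared_factor": shared,
        "is_drought": dry,
    })
    return grid, truth


def simulate_dataset(cfg: SimulationConfig | None = None) -> dict[str, pd.DataFrame]:
    """Run the full generator; returns all tables keyed by name.

    Keys: ``trees, plots, climate_grid, truth_species_year, truth_plots,
    truth_climate``. Fully deterministic under ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rngs = _rngs(cfg)
    plots, truth_plots = simulate_plot_environments(cfg, rngs["plots"])
    trees, truth_sy = simulate_trees(cfg, truth_plots, rngs["trees"])
    grid, truth_climate = simulate_climate_grid(cfg, rngs["climate"])
    return {
        "trees": trees, "plots": plots, "climate_grid": grid,
        "truth_species_year": truth_sy, "truth_plots": truth_plots,
        "truth_climate": truth_climate,
    }
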