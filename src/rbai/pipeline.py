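"""End-to-end pipeline: climate → increments → chronologies → trends →
cohort curves → ordination, with a manifest for reproducibility.

A run consumes the three input tables (trees, plots, climate grid), executes
every stage under a single master seed and writes all output CSVs plus a
manifest (input checksums, seed, package version) and the resolved
configuration. Identical configuration and inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import chronology as chron
from . import climate as clim
from . import growth, ordination, trends
from .io import (read_circumference_table, read_climate_grid, read_plot_table,
                 write_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    trees_path: str = "trees.csv"
    plots_path: str = "plots.csv"
    climate_grid_path: str = "climate_grid.csv"
    out_dir: str = "out"
    normal_period: tuple = (1950, 2021)
    dry_threshold: float = 0.90
    #: override the detector with a fixed dry-year list (None = detect)
    dry_years_override: tuple | None = None
    study_years: tuple = (1989, 2023)
    class_width_cm: float = 5.0
    min_class_count: int = 5
    rbai_denominator: str = "current"
    bootstrap_per_class: int = 5
    bootstrap_reps: int = 20
    gam_k: int = 4
    gam_min_records: int = 50
    gam_periods: tuple = ((1990, 2021), (2000, 2021), (2010, 2021))
    gam_dbh_values: tuple = (20.0, 30.0, 40.0)
    pca_scale: bool = True
    envfit_permutations: int = 999
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        # YAML round-trips tuples as lists; normalize
        for f in ("normal_period", "study_years", "gam_dbh_values"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        cfg.gam_periods = tuple(tuple(p) for p in cfg.gam_periods)
        if cfg.dry_years_override is not None:
            cfg.dry_years_override = tuple(cfg.dry_years_override)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Outputs: ``plot_climate.csv, dry_years.csv, increments.csv,
    chronology.csv, trends.csv, cohort_curves.csv, scores.csv,
    centroids.csv, ellipses.csv, envfit.csv, manifest.json, config.yaml``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    trees = read_circumference_table(config.trees_path)
    plots = read_plot_table(config.plots_path)
    grid = read_climate_grid(config.climate_grid_path)

    # --- climate ---------------------------------------------------------
    plot_climate = clim.interpolate_all_plots(grid, plots)
    write_table(plot_climate, out / "plot_climate.csv")
    report = clim.detect_dry_years(plot_climate, config.normal_period,
                                   config.dry_threshold, config.study_years)
    dry_years = (list(config.dry_years_override)
                 if config.dry_years_override is not None else report.dry_years)
    dry_df = report.fractions.copy()
    dry_df["is_dry"] = dry_df["year"].isin(dry_years)
    write_table(dry_df, out / "dry_years.csv")
    logger.info("dry years: %s", dry_years)

    # --- increments and chronologies ------------------------------------
    incr = growth.compute_increments(trees, denominator=config.rbai_denominator)
    incr = growth.assign_circ_classes(incr, config.class_width_cm,
                                      config.min_class_count)
    write_table(incr, out / "increments.csv")

    params = chron.BootstrapParams(config.bootstrap_per_class,
                                   config.bootstrap_reps, config.seed)
    chronos = pd.concat(
        [chron.build_chronology(incr, sp, params)
         for sp in sorted(incr["species"].unique())],
        ignore_index=True,
    )
    write_table(chronos, out / "chronology.csv")

    trend_table = trends.fit_trends(chronos)
    write_table(trend_table, out / "trends.csv")

    # --- cohort curves ---------------------------------------------------
    curves = trends.cohort_curves(
        incr, periods=config.gam_periods, dbh_values=config.gam_dbh_values,
        k=config.gam_k, min_records=config.gam_min_records,
    )
    write_table(curves, out / "cohort_curves.csv")

    # --- ordination ------------------------------------------------------
    matrix = ordination.build_dry_year_matrix(incr, dry_years)
    result = ordination.run_pca(matrix, scale=config.pca_scale)
    ordination.species_centroids_ellipses(result)
    env = plots.merge(
        plot_climate[plot_climate["year"].between(*config.study_years)]
        .groupby("plot_id")[["temp_ann_c", "precip_ann_mm"]].mean()
        .reset_index(),
        on="plot_id", how="left",
    )
    ordination.envfit(result, env, n_perm=config.envfit_permutations,
                      seed=config.seed)
    scores = result.scores.reset_index()
    scores = scores.merge(ordination.tag_extreme_plots(matrix),
                          on=["plot_id", "species"])
    write_table(scores, out / "scores.csv")
    write_table(result.centroids, out / "centroids.csv")
    write_table(result.ellipses, out / "ellipses.csv")
    write_table(result.envfit, out / "envfit.csv")

    # --- manifest --------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: _sha256(Path(p)) for name, p in [
                ("trees", config.trees_path), ("plots", config.plots_path),
                ("climate_grid", config.climate_grid_path),
            ]
        },
        "dry_years": [int(y) for y in dry_years],
        "outputs": sorted(p.name for p in out.glob("*.csv")),
        "explained_pct": [round(float(x), 6)
                          for x in result.explained_pct[:2]],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return out
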