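"""Basal area, basal-area increment (BAI) and relative BAI (RBAI).

Stem circumference ``c`` (cm, over bark at breast height) converts to basal
area ``BA = c² / (4π)`` (cm²). The annual increment attributed to year *t* is
``BAI_t = BA_t − BA_{t−1}`` for consecutive survey years, and the relative
increment is expressed against the basal area in the year of measurement:

    RBAI_t = 100 · BAI_t / BA_t   (%)

RBAI removes the absolute-size effect, so trees of different diameters are
comparable; a previous-year denominator is available behind a flag. Negative
increments (shrinkage or measurement error) are retained but flagged —
truncating them would bias trends upward.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def basal_area(circumference_cm):
    """Basal area in cm² from stem circumference in cm: ``c²/(4π)``."""
    c = np.asarray(circumference_cm, dtype=float)
    if (c < 0).any():
        raise ValueError("circumference must be non-negative")
    out = c * c / (4.0 * np.pi)
    return out if out.ndim else float(out)


def compute_increments(trees: pd.DataFrame, denominator: str = "current") -> pd.DataFrame:
    """Derive per-tree annual increments from a circumference table.

    Parameters
    ----------
    trees
        Validated circumference table (see :mod:`rbai.io`).
    denominator
        ``"current"`` — RBAI relative to the basal area of the measurement
        year t (default); ``"previous"`` — relative to year t−1.

    Returns
    -------
    DataFrame with one row per tree-year that has a consecutive predecessor:
    ``plot_id, tree_id, species, year, circumference_cm, dbh_cm,
    basal_area_cm2, bai_cm2, rbai_pct, negative_bai`` (bool flag).
    Mid-series gaps (non-consecutive years) yield no increment.
    """
    if denominator not in ("current", "previous"):
        raise ValueError("denominator must be 'current' or 'previous'")
    df = trees.sort_values(["plot_id", "tree_id", "year"]).reset_index(drop=True)
    ba = basal_area(df["circumference_cm"].to_numpy())
    grp = df.groupby(["plot_id", "tree_id"], sort=False)
    prev_year = grp["year"].shift(1)
    prev_ba = pd.Series(ba, index=df.index).groupby(
        [df["plot_id"], df["tree_id"]], sort=False
    ).shift(1)

    consecutive = (df["year"] - prev_year) == 1
    out = df.loc[consecutive].copy()
    out["basal_area_cm2"] = ba[consecutive.to_numpy()]
    out["dbh_cm"] = out["circumference_cm"] / np.pi
    out["bai_cm2"] = out["basal_area_cm2"] - prev_ba[consecutive].to_numpy()
    denom = out["basal_area_cm2"] if denominator == "current" else prev_ba[consecutive].to_numpy()
    out["rbai_pct"] = 100.0 * out["bai_cm2"] / denom
    out["negative_bai"] = out["bai_cm2"] < 0
    n_neg = int(out["negative_bai"].sum())
    if n_neg:
        logger.info("retained %d negative increments (flagged)", n_neg)
    return out.reset_index(drop=True)


def _merge_small_classes(classes: np.ndarray, min_count: int) -> np.ndarray:
    """Merge classes with < min_count members into the nearest neighbour
    class (by class index; ties go to the lower index). Operates on one
    species×year group."""
    classes = classes.copy()
    while True:
        uniq, counts = np.unique(classes, return_counts=True)
        if len(uniq) <= 1:
            break
        small = np.where(counts < min_count)[0]
        if len(small) == 0:
            break
        # merge the smallest offending class first for determinism
        i = small[np.argmin(counts[small])]
        others = np.delete(uniq, i)
        dist = np.abs(others - uniq[i])
        target = others[np.argmin(dist)]  # argmin takes lower index on ties
        classes[classes == uniq[i]] = target
    return classes


def assign_circ_classes(
    increments: pd.DataFrame,
    class_width_cm: float = 5.0,
    min_class_count: int | None = 5,
) -> pd.DataFrame:
    """Assign 5 cm circumference classes, merged per species×year where thin.

    The raw class index is ``floor(circumference_cm / width)`` on half-open
    intervals [lower, upper). Within each species×year group, classes holding
    fewer than ``min_class_count`` increment records are folded into the
    nearest neighbouring class so every stratum can support resampling; pass
    ``min_class_count=None`` to keep raw classes. The effective number of
    classes therefore adapts to each species' size spread.
    """
    if class_width_cm <= 0:
        raise ValueError("class_width_cm must be positive")
    out = increments.copy()
    out["circ_class"] = np.floor(
        out["circumference_cm"].to_numpy() / class_width_cm
    ).astype(int)
    if min_class_count is not None:
        merged = np.empty(len(out), dtype=int)
        for _, idx in out.groupby(["species", "year"], sort=False).indices.items():
            merged[idx] = _merge_small_classes(
                out["circ_class"].to_numpy()[idx], min_class_count
            )
        out["circ_class"] = merged
    return out
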