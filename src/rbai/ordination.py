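"""Ordination of growth in dry years: PCA, species ellipses, vector fitting.

The unit of analysis is the (plot, species) pair; its profile is the mean
RBAI of that species' trees on that plot in each selected dry year. PCA of
the (optionally standardized) profile matrix summarises how sites and
species co-vary in their drought-year growth; species centroids and 95%
bivariate-normal ellipses in PC1–PC2 space describe the position and spread
of each species' drought response.

Environmental-vector fitting ("envfit" in the vegan sense): each site
variable *v* is regressed on the (PC1, PC2) scores by least squares; the
squared multiple correlation R² measures how much of *v*'s variation aligns
with the ordination plane, and its significance comes from a permutation
test shuffling *v* across rows — p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm).
Arrow directions are the normalized regression coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENVFIT_VARIABLES = (
    "elevation_m", "aspect_deg", "slope_deg", "tree_richness", "pH_H2O",
    "clay_pct", "silt_pct", "sand_pct", "total_N", "organic_C", "c_n_ratio",
    "precip_ann_mm", "temp_ann_c",
)


def build_dry_year_matrix(increments: pd.DataFrame, dry_years) -> pd.DataFrame:
    """Rows (plot_id, species) × columns dry years; cells = mean RBAI (%).

    Complete-case: rows missing any selected dry-year column are dropped
    (and logged), matching the requirement that every profile covers all
    selected years.
    """
    dry_years = sorted(int(y) for y in dry_years)
    if not dry_years:
        raise ValueError("dry_years is empty")
    sub = increments[increments["year"].isin(dry_years)]
    mat = (sub.groupby(["plot_id", "species", "year"])["rbai_pct"].mean()
           .unstack("year"))
    mat = mat.reindex(columns=dry_years)
    complete = mat.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropped %d incomplete (plot, species) rows from the "
                    "dry-year matrix", int((~complete).sum()))
    mat = mat[complete]
    if mat.empty:
        raise ValueError("no complete (plot, species) rows for the selected dry years")
    return mat


@dataclass
class OrdinationResult:
    scores: pd.DataFrame            # index (plot_id, species); columns PC1..PCk
    loadings: pd.DataFrame          # index dry years; columns PC1..PCk
    explained_pct: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    centroids: pd.DataFrame | None = None
    ellipses: pd.DataFrame | None = None
    envfit: pd.DataFrame | None = None


def run_pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> OrdinationResult:
    """PCA by singular value decomposition of the standardized matrix.

    ``scale=True`` divides columns by their sd (ddof=1), i.e. PCA of the
    correlation matrix. Sign convention: the largest-magnitude element of
    each loading vector is made positive. Scores are the projections of the
    standardized rows on the loading vectors (eigenvalue-scaled, prcomp-style).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 complete rows and 2 columns for PCA")
    mu = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        const = np.where(sd == 0)[0]
        if len(const):
            raise ValueError(
                f"constant column(s) under scaling: {list(matrix.columns[const])}"
            )
    else:
        sd = np.ones(p)
    Z = Xc / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eig = S ** 2 / (n - 1)
    explained = 100.0 * eig / eig.sum()
    names = [f"PC{j + 1}" for j in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.index, columns=names)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=names)
    return OrdinationResult(scores=scores, loadings=loadings,
                            explained_pct=explained, center=mu, scale=sd)


def species_centroids_ellipses(
    result: OrdinationResult,
    confidence: float = 0.95,
    method: str = "normal",
) -> OrdinationResult:
    """Per-species centroid and 95% region of the (PC1, PC2) scores.

    ``method="normal"`` (default): bivariate-normal probability ellipse at
    the χ²₂ quantile of the species' score covariance. ``method="rect"``:
    literal per-axis percentile rectangle (reported via half-widths, zero
    rotation). Species with <3 rows get a centroid only (warned).
    """
    if method not in ("normal", "rect"):
        raise ValueError("method must be 'normal' or 'rect'")
    sc = result.scores[["PC1", "PC2"]].reset_index()
    cents, ells = [], []
    for sp, g in sc.groupby("species"):
        cx, cy = g["PC1"].mean(), g["PC2"].mean()
        cents.append({"species": sp, "pc1": cx, "pc2": cy, "n": len(g)})
        if len(g) < 3:
            logger.warning("species %s has %d rows; centroid only", sp, len(g))
            continue
        if method == "rect":
            a = (1 - confidence) / 2 * 100
            lo1, hi1 = np.percentile(g["PC1"], [a, 100 - a])
            lo2, hi2 = np.percentile(g["PC2"], [a, 100 - a])
            ells.append({"species": sp, "center_pc1": (lo1 + hi1) / 2,
                         "center_pc2": (lo2 + hi2) / 2,
                         "semi_axis_1": (hi1 - lo1) / 2,
                         "semi_axis_2": (hi2 - lo2) / 2,
                         "angle_deg": 0.0, "degenerate": hi1 == lo1 or hi2 == lo2})
            continue
        cov = np.cov(g[["PC1", "PC2"]].to_numpy().T, ddof=1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        degenerate = bool(np.any(eigval <= 1e-12))
        q = stats.chi2.ppf(confidence, df=2)
        semi = np.sqrt(np.clip(eigval, 0, None) * q)
        angle = math.degrees(math.atan2(eigvec[1, 0], eigvec[0, 0]))
        ells.append({"species": sp, "center_pc1": cx, "center_pc2": cy,
                     "semi_axis_1": semi[0], "semi_axis_2": semi[1],
                     "angle_deg": angle, "degenerate": degenerate})
        if degenerate:
            logger.warning("species %s: degenerate (rank-deficient) ellipse", sp)
    result.centroids = pd.DataFrame(cents)
    result.ellipses = pd.DataFrame(ells)
    return result


def ellipse_contains(ellipse: pd.Series, pc1, pc2) -> np.ndarray:
    """Membership test for points against one fitted ellipse row."""
    th = math.radians(ellipse["angle_deg"])
    dx, dy = np.asarray(pc1) - ellipse["center_pc1"], np.asarray(pc2) - ellipse["center_pc2"]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / ellipse["semi_axis_1"]) ** 2 + (v / ellipse["semi_axis_2"]) ** 2 <= 1.0


def _r2_and_coefs(scores: np.ndarray, v: np.ndarray):
    """R² and direction cosines of v ~ PC1 + PC2 (least squares)."""
    X = np.column_stack([np.ones(len(v)), scores])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    ss_tot = np.sum((v - v.mean()) ** 2)
    if ss_tot == 0:
        return 0.0, np.zeros(scores.shape[1])
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    b = beta[1:]
    norm = np.linalg.norm(b)
    return float(max(r2, 0.0)), (b / norm if norm > 0 else b)


def envfit(
    result: OrdinationResult,
    environments: pd.DataFrame,
    variables=ENVFIT_VARIABLES,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Fit environmental vectors onto the (PC1, PC2) plane with permutation p.

    ``environments`` is joined to the score rows by plot_id (plot-level
    covariates are duplicated across species sharing a plot, pooling species
    as in a network-wide analysis). Missing values are handled case-wise per
    variable. ``exhaustive=True`` enumerates all row permutations (only
    sensible for tiny n). Constant variables get R²=0, p=1 with a warning.

    Returns a table ``variable, r2_pct, p_value, mark, arrow_pc1, arrow_pc2, n``.
    """
    rng = np.random.default_rng(seed)
    sc = result.scores[["PC1", "PC2"]].reset_index()
    env = environments.set_index("plot_id")
    rows = []
    for var in variables:
        if var not in env.columns:
            logger.warning("variable %s absent from environments; skipped", var)
            continue
        v_all = env[var].reindex(sc["plot_id"]).to_numpy(dtype=float)
        mask = np.isfinite(v_all)
        v = v_all[mask]
        S = sc.loc[mask, ["PC1", "PC2"]].to_numpy()
        if len(v) < 3 or np.ptp(v) == 0:
            logger.warning("variable %s constant or too few cases; R2=0, p=1", var)
            rows.append({"variable": var, "r2_pct": 0.0, "p_value": 1.0,
                         "mark": "", "arrow_pc1": 0.0, "arrow_pc2": 0.0,
                         "n": int(len(v))})
            continue
        r2, arrow = _r2_and_coefs(S, v)
        if exhaustive:
            from itertools import permutations
            perms = np.array(list(permutations(range(len(v)))))
            r2_perm = np.array([_r2_and_coefs(S, v[p])[0] for p in perms])
            p_val = float(np.mean(r2_perm >= r2 - 1e-12))
        else:
            hits = 0
            for _ in range(n_perm):
                r2p, _a = _r2_and_coefs(S, rng.permutation(v))
                hits += r2p >= r2 - 1e-12
            p_val = (1 + hits) / (1 + n_perm)
        mark = "*" if p_val < 0.05 else ("." if p_val < 0.1 else "")
        rows.append({"variable": var, "r2_pct": 100 * r2, "p_value": p_val,
                     "mark": mark, "arrow_pc1": arrow[0], "arrow_pc2": arrow[1],
                     "n": int(len(v))})
    out = pd.DataFrame(rows)
    result.envfit = out
    return out


def tag_extreme_plots(matrix: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Tag the best- and worst-growing rows over the dry years.

    Rows are ranked by their mean RBAI across the selected dry years; the top
    ``fraction`` are tagged "highest", the bottom ``fraction`` "lowest".
    """
    mean = matrix.mean(axis=1)
    k = max(1, int(round(fraction * len(mean))))
    order = mean.sort_values()
    tag = pd.Series("", index=matrix.index, name="growth_tag")
    tag.loc[order.index[:k]] = "lowest"
    tag.loc[order.index[-k:]] = "highest"
    return tag.reset_index()
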