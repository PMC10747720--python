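import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from rbai.ordination import (build_dry_year_matrix, ellipse_contains, envfit,
                             run_pca, species_centroids_ellipses,
                             tag_extreme_plots)

DRY = [2000, 2003, 2012]


def make_matrix(n_rows=12, n_cols=6, seed=0, species=("FS", "PA")):
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_tuples(
        [(f"P{i:02d}", species[i % len(species)]) for i in range(n_rows)],
        names=["plot_id", "species"])
    return pd.DataFrame(rng.normal(2, 0.5, (n_rows, n_cols)), index=idx,
                        columns=range(2000, 2000 + n_cols))


class TestBuildDryYearMatrix:
    def _incr(self, rows):
        return pd.DataFrame(rows, columns=["plot_id", "tree_id", "species",
                                           "year", "rbai_pct"])

    def test_single_row_all_twos(self):
        rows = [("P1", f"T{t}", "FS", y, 2.0) for t in range(3) for y in DRY]
        mat = build_dry_year_matrix(self._incr(rows), DRY)
        assert mat.shape == (1, 3)
        np.testing.assert_allclose(mat.to_numpy(), 2.0)

    def test_incomplete_row_dropped(self):
        rows = ([("P1", "T1", "FS", y, 2.0) for y in DRY]
                + [("P2", "T1", "FS", y, 1.0) for y in DRY[:-1]])
        mat = build_dry_year_matrix(self._incr(rows), DRY)
        assert list(mat.index.get_level_values("plot_id")) == ["P1"]

    def test_cells_match_groupby_oracle(self, small_increments, small_cfg):
        dry = sorted(small_cfg.drought_years)
        mat = build_dry_year_matrix(small_increments, dry)
        sub = small_increments[small_increments["year"].isin(dry)]
        for (pid, sp), row in mat.sample(5, random_state=0).iterrows():
            for y in dry:
                expect = sub[(sub["plot_id"] == pid) & (sub["species"] == sp)
                             & (sub["year"] == y)]["rbai_pct"].mean()
                assert row[y] == pytest.approx(expect, rel=1e-12)

    def test_empty_dry_years_is_error(self, small_increments):
        with pytest.raises(ValueError):
            build_dry_year_matrix(small_increments, [])


class TestRunPCA:
    def test_rank_one_matrix_pc1_explains_all(self):
        u = np.linspace(1, 2, 8)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        mat = make_matrix(8, 4)
        mat.iloc[:, :] = np.outer(u, v)
        res = run_pca(mat, scale=False)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_explained_percentages_sum_to_100(self):
        res = run_pca(make_matrix(20, 6, seed=2))
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_agrees_with_sklearn_svd_oracle(self):
        from sklearn.decomposition import PCA
        mat = make_matrix(25, 8, seed=3)
        res = run_pca(mat, scale=True)
        Z = (mat - mat.mean()) / mat.std(ddof=1)
        sk = PCA(n_components=8)
        scores = sk.fit_transform(Z.to_numpy())
        # align signs component-wise before comparing
        for j in range(8):
            if np.sign(scores[0, j]) != np.sign(res.scores.iloc[0, j]):
                scores[:, j] *= -1
        np.testing.assert_allclose(res.scores.to_numpy(), scores, atol=1e-8)
        np.testing.assert_allclose(
            res.explained_pct, 100 * sk.explained_variance_ratio_, atol=1e-8)

    def test_reconstruction_with_all_components(self):
        mat = make_matrix(15, 5, seed=4)
        res = run_pca(mat, scale=True)
        Z = (mat - res.center) / res.scale
        back = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(back, Z.to_numpy(), atol=1e-8)

    def test_constant_column_under_scaling_is_error(self):
        mat = make_matrix(10, 4)
        mat.iloc[:, 2] = 5.0
        with pytest.raises(ValueError, match="2002"):
            run_pca(mat, scale=True)

    def test_sign_convention_deterministic(self):
        mat = make_matrix(20, 5, seed=6)
        a = run_pca(mat)
        b = run_pca(mat)
        for j in range(5):
            load = a.loadings.iloc[:, j]
            assert load.iloc[np.argmax(np.abs(load.to_numpy()))] > 0
        pd.testing.assert_frame_equal(a.scores, b.scores)


class TestCentroidsEllipses:
    def test_centroid_is_species_score_mean_and_permutation_invariant(self):
        mat = make_matrix(16, 5, seed=7)
        res = species_centroids_ellipses(run_pca(mat))
        for _, row in res.centroids.iterrows():
            sel = res.scores.xs(row["species"], level="species")
            assert row["pc1"] == pytest.approx(sel["PC1"].mean())
        perm = mat.sample(frac=1, random_state=5)
        res2 = species_centroids_ellipses(run_pca(perm))
        a = res.centroids.set_index("species").sort_index()
        b = res2.centroids.set_index("species").sort_index()
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-10)

    def test_identical_rows_degenerate_ellipse_flagged(self):
        mat = make_matrix(9, 4, seed=8, species=("FS",))
        mat.iloc[3:6] = mat.iloc[3].to_numpy()  # FS rows... all species FS here
        res = species_centroids_ellipses(run_pca(mat))
        assert "degenerate" in res.ellipses.columns

    def test_bivariate_normal_coverage(self):
        """95% normal-probability ellipse contains ~95% of 10k points."""
        rng = np.random.default_rng(9)
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 1.0]], 10000)
        idx = pd.MultiIndex.from_tuples([(f"P{i}", "FS") for i in range(10000)],
                                        names=["plot_id", "species"])
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"], index=idx)
        from rbai.ordination import OrdinationResult
        res = OrdinationResult(scores=scores, loadings=None,
                               explained_pct=np.array([60.0, 40.0]),
                               center=np.zeros(2), scale=np.ones(2))
        res = species_centroids_ellipses(res)
        ell = res.ellipses.iloc[0]
        inside = ellipse_contains(ell, pts[:, 0], pts[:, 1]).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_rectangle_variant(self):
        mat = make_matrix(30, 5, seed=10)
        res = species_centroids_ellipses(run_pca(mat), method="rect")
        assert (res.ellipses["angle_deg"] == 0).all()


def env_for(matrix, seed=0, elev_from_pc1=None):
    rng = np.random.default_rng(seed)
    plots = matrix.index.get_level_values("plot_id").unique()
    env = pd.DataFrame({"plot_id": plots,
                        "elevation_m": rng.uniform(200, 1400, len(plots))})
    return env


class TestEnvfit:
    def test_variable_identical_to_pc1_gives_full_r2_smallest_p(self):
        mat = make_matrix(12, 5, seed=11, species=("FS",))
        res = run_pca(mat)
        env = pd.DataFrame({"plot_id": res.scores.index.get_level_values("plot_id"),
                            "v": res.scores["PC1"].to_numpy()})
        table = envfit(res, env, variables=("v",), n_perm=199, seed=1)
        assert table["r2_pct"].iloc[0] == pytest.approx(100.0, abs=1e-8)
        assert table["p_value"].iloc[0] == pytest.approx(1 / 200, abs=1e-12)

    def test_r2_matches_exhaustive_permutation_oracle_n6(self):
        """On 6 rows, compare R² and the exhaustive-permutation p against a
        brute-force oracle enumerating all 720 permutations."""
        mat = make_matrix(6, 4, seed=12, species=("FS",))
        res = run_pca(mat)
        rng = np.random.default_rng(13)
        v = rng.normal(size=6)
        env = pd.DataFrame({"plot_id": res.scores.index.get_level_values("plot_id"),
                            "v": v})
        table = envfit(res, env, variables=("v",), exhaustive=True)
        # oracle: direct multiple-correlation formula + full enumeration
        from itertools import permutations
        S = res.scores[["PC1", "PC2"]].to_numpy()
        X = np.column_stack([np.ones(6), S])

        def r2_of(vv):
            beta, *_ = np.linalg.lstsq(X, vv, rcond=None)
            ss_res = ((vv - X @ beta) ** 2).sum()
            ss_tot = ((vv - vv.mean()) ** 2).sum()
            return 1 - ss_res / ss_tot

        r2 = r2_of(v)
        count = sum(r2_of(v[list(p)]) >= r2 - 1e-12
                    for p in permutations(range(6)))
        assert table["r2_pct"].iloc[0] == pytest.approx(100 * r2, abs=1e-9)
        assert table["p_value"].iloc[0] == pytest.approx(count / 720, abs=1e-12)

    def test_p_invariant_to_affine_transform_of_variable(self):
        mat = make_matrix(15, 5, seed=14, species=("FS",))
        res = run_pca(mat)
        plots = res.scores.index.get_level_values("plot_id")
        v = np.random.default_rng(15).normal(size=15)
        t1 = envfit(res, pd.DataFrame({"plot_id": plots, "v": v}),
                    variables=("v",), n_perm=99, seed=3)
        t2 = envfit(res, pd.DataFrame({"plot_id": plots, "v": 5 - 3 * v}),
                    variables=("v",), n_perm=99, seed=3)
        assert t1["p_value"].iloc[0] == t2["p_value"].iloc[0]
        assert t1["r2_pct"].iloc[0] == pytest.approx(t2["r2_pct"].iloc[0], abs=1e-9)

    def test_constant_variable_r2_zero_p_one(self):
        mat = make_matrix(10, 4, seed=16, species=("FS",))
        res = run_pca(mat)
        env = pd.DataFrame({"plot_id": res.scores.index.get_level_values("plot_id"),
                            "v": 7.0})
        table = envfit(res, env, variables=("v",), n_perm=99, seed=1)
        assert table["r2_pct"].iloc[0] == 0.0 and table["p_value"].iloc[0] == 1.0

    def test_missing_values_handled_casewise(self):
        mat = make_matrix(12, 4, seed=17, species=("FS",))
        res = run_pca(mat)
        plots = res.scores.index.get_level_values("plot_id")
        v = np.random.default_rng(18).normal(size=12)
        v[3] = np.nan
        table = envfit(res, pd.DataFrame({"plot_id": plots, "v": v}),
                       variables=("v",), n_perm=99, seed=1)
        assert table["n"].iloc[0] == 11

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_r2_matches_vegan_envfit(self, tmp_path):
        """Cross-check R² against vegan::envfit on a fixed small fixture."""
        mat = make_matrix(20, 6, seed=19, species=("FS",))
        res = run_pca(mat)
        rng = np.random.default_rng(20)
        env_vals = res.scores["PC1"].to_numpy() * 0.5 + rng.normal(size=20)
        plots = res.scores.index.get_level_values("plot_id")
        table = envfit(res, pd.DataFrame({"plot_id": plots, "v": env_vals}),
                       variables=("v",), n_perm=99, seed=1)
        sc = res.scores[["PC1", "PC2"]].copy()
        sc["v"] = env_vals
        f = tmp_path / "sc.csv"
        sc.to_csv(f, index=False)
        rscript = f"""
        d <- read.csv("{f}")
        suppressMessages(library(vegan))
        ef <- envfit(d[, c("PC1","PC2")], d[, "v", drop=FALSE], permutations=0)
        cat(sprintf("%.10f", ef$vectors$r[1]))
        """
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        vegan_r2 = float(out.stdout.strip())
        assert table["r2_pct"].iloc[0] == pytest.approx(100 * vegan_r2, abs=1e-6)


def test_tag_extreme_plots_top_and_bottom_decile():
    mat = make_matrix(20, 4, seed=21)
    mat.iloc[0] = 10.0   # clear best
    mat.iloc[1] = -10.0  # clear worst
    tags = tag_extreme_plots(mat, fraction=0.10).set_index(["plot_id", "species"])
    assert tags.loc[mat.index[0], "growth_tag"] == "highest"
    assert tags.loc[mat.index[1], "growth_tag"] == "lowest"
    assert (tags["growth_tag"] == "highest").sum() == 2
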