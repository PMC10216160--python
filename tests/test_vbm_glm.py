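"""GLM correctness against closed forms, clustering, and permutation FWE."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from bntvbm.vbm_glm import (
    CONNECTIVITY_18,
    ClusterResult,
    ContrastSpec,
    StatMap,
    build_design,
    cluster_fwe,
    fit_voxelwise,
    form_clusters,
    report_clusters,
    smooth_map,
)


def _scores_frame(n, rng):
    return pd.DataFrame(
        {
            "quantitative": rng.normal(23, 3, n),
            "qualitative": rng.normal(4.9, 0.3, n),
            "education": rng.normal(16, 3, n),
            "brain_parenchymal_ratio": rng.uniform(0.6, 0.9, n),
            "left_hippocampus_ml": rng.normal(3.5, 0.4, n),
            "age": rng.normal(75, 6, n),
            "roi_volume": rng.normal(3.5, 0.4, n),
            "icv_ml": rng.normal(1450, 100, n),
            "gm_ratio": rng.uniform(0.35, 0.45, n),
        }
    )


class TestBuildDesign:
    def test_model1_composition(self):
        X, con = build_design(_scores_frame(100, np.random.default_rng(0)), "model1")
        assert X.shape == (100, 6)
        assert list(X.columns)[:2] == ["intercept", "quantitative"]
        assert con.direction == "positive"
        assert con.weights[X.columns.get_loc("quantitative")] == 1.0
        # centred covariates
        assert abs(X["age"].mean()) < 1e-10

    def test_model2_composition(self):
        X, con = build_design(_scores_frame(100, np.random.default_rng(0)), "model2")
        assert X.shape == (100, 7)
        assert "quantitative" in X.columns  # fifth covariate
        assert con.direction == "negative"

    def test_structcov_composition(self):
        X, con = build_design(_scores_frame(60, np.random.default_rng(0)), "structcov")
        assert list(X.columns) == ["intercept", "roi_volume", "age", "icv_ml", "gm_ratio"]
        assert con.direction == "positive"

    def test_collinear_columns_named(self):
        df = _scores_frame(100, np.random.default_rng(0))
        df["education"] = df["age"] * 2.0  # exact collinearity after centring
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(df, "model1")

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            build_design(_scores_frame(12, np.random.default_rng(0)), "model1")


class TestFitVoxelwise:
    def test_matches_closed_form_on_random_designs(self):
        """Independent oracle: beta via lstsq, covariance via explicit
        (X'X)^-1, on 50 random small designs; agreement to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(12, 21))
            p = int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            V = 5
            Y = rng.standard_normal((n, V))
            c = np.zeros(p)
            c[int(rng.integers(0, p))] = 1.0
            mask = np.ones((V, 1, 1), dtype=bool)
            sm = fit_voxelwise(Y, X, ContrastSpec(c, "positive"), mask)
            beta_hat, res, *_ = np.linalg.lstsq(X, Y, rcond=None)
            rss = ((Y - X @ beta_hat) ** 2).sum(axis=0)
            sigma2 = rss / (n - p)
            se = np.sqrt(sigma2 * (c @ np.linalg.inv(X.T @ X) @ c))
            t_oracle = (c @ beta_hat) / se
            np.testing.assert_allclose(sm.t[mask], t_oracle, rtol=1e-10, atol=1e-10)
            assert sm.df == n - p

    def test_null_t_distribution(self):
        """Under a planted null, voxelwise t values follow Student t(df)."""
        rng = np.random.default_rng(7)
        n, V = 40, 4000
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        Y = rng.standard_normal((n, V))
        c = np.array([0.0, 1.0, 0.0])
        mask = np.ones((V, 1, 1), dtype=bool)
        sm = fit_voxelwise(Y, X, ContrastSpec(c, "positive"), mask)
        ks = stats.kstest(sm.t[mask], stats.t(df=sm.df).cdf)
        assert ks.pvalue > 0.01

    def test_contrast_direction_flips_t_sign_not_value(self):
        rng = np.random.default_rng(1)
        n, V = 30, 10
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, V))
        mask = np.ones((V, 1, 1), dtype=bool)
        pos = fit_voxelwise(Y, X, ContrastSpec(np.array([0, 1.0]), "positive"), mask)
        negc = fit_voxelwise(Y, X, ContrastSpec(np.array([0, -1.0]), "positive"), mask)
        np.testing.assert_allclose(negc.t, -pos.t, rtol=1e-12)

    def test_zero_variance_voxels_flagged(self):
        rng = np.random.default_rng(2)
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, 3))
        Y[:, 1] = 5.0  # constant voxel: zero residual variance
        mask = np.ones((3, 1, 1), dtype=bool)
        sm = fit_voxelwise(Y, X, ContrastSpec(np.array([0, 1.0]), "positive"), mask)
        assert not sm.mask[1, 0, 0]
        assert np.isnan(sm.t[1, 0, 0])


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 8))
        np.testing.assert_array_equal(smooth_map(img, 0.0, 4.0), img)

    def test_sigma_from_fwhm(self):
        """A centred delta smoothed at FWHM f has the discrete Gaussian
        profile with sigma = f / (2 sqrt(2 ln 2)) voxels."""
        img = np.zeros((31, 31, 31))
        img[15, 15, 15] = 1.0
        out = smooth_map(img, 6.0, 4.0)
        sigma = 6.0 / (2 * math.sqrt(2 * math.log(2))) / 4.0
        assert sigma == pytest.approx(0.6369, abs=1e-4)
        profile = out[15, 15, 13:18]
        expect = np.exp(-((np.arange(-2, 3)) ** 2) / (2 * sigma**2))
        expect = expect / expect.sum() * profile.sum()
        np.testing.assert_allclose(profile, expect, rtol=0.05)

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12, 12))
        out = smooth_map(img, 10.0, 2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((8, 8, 8)), -1.0, 4.0)


def _statmap_from_t(t3, df=30, direction="positive"):
    mask = np.isfinite(t3)
    sign = 1.0 if direction == "positive" else -1.0
    z = stats.norm.isf(stats.t.sf(sign * t3, df))
    return StatMap(beta=t3, t=t3, z=z, df=df, mask=mask, direction=direction)


class TestFormClusters:
    def test_face_adjacent_voxels_join(self):
        t = np.zeros((6, 6, 6))
        t[2, 2, 2] = t[2, 2, 3] = 10.0
        labels, extents, _ = form_clusters(_statmap_from_t(t), 0.01)
        assert len(extents) == 1 and extents[0] == 2

    def test_edge_adjacent_join_but_corner_split(self):
        t = np.zeros((6, 6, 6))
        t[1, 1, 1] = 10.0
        t[2, 2, 1] = 10.0  # edge neighbour (two indices differ): joined at 18-conn
        t[4, 4, 4] = 10.0  # far away
        labels, extents, _ = form_clusters(_statmap_from_t(t), 0.01)
        assert sorted(extents, reverse=True) == [2, 1]
        t2 = np.zeros((6, 6, 6))
        t2[1, 1, 1] = 10.0
        t2[2, 2, 2] = 10.0  # corner neighbour (all three differ): split
        _, extents2, _ = form_clusters(_statmap_from_t(t2), 0.01)
        assert list(extents2) == [1, 1]

    def test_opposite_corners_two_clusters(self):
        t = np.zeros((8, 8, 8))
        t[0, 0, 0] = t[7, 7, 7] = 10.0
        _, extents, _ = form_clusters(_statmap_from_t(t), 0.01)
        assert list(extents) == [1, 1]

    def test_empty_suprathreshold_set(self):
        labels, extents, _ = form_clusters(_statmap_from_t(np.zeros((6, 6, 6))), 0.01)
        assert labels.max() == 0 and len(extents) == 0

    def test_null_suprathreshold_fraction_near_nominal(self):
        """All-null maps: about p_form of in-mask voxels exceed the
        cluster-forming threshold."""
        rng = np.random.default_rng(9)
        n, shape = 40, (12, 12, 12)
        V = int(np.prod(shape))
        fracs = []
        for _ in range(20):
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            Y = rng.standard_normal((n, V))
            sm = fit_voxelwise(
                Y, X, ContrastSpec(np.array([0, 1.0]), "positive"),
                np.ones(shape, bool),
            )
            _, extents, tcrit = form_clusters(sm, 0.01)
            fracs.append((sm.t >= tcrit).sum() / V)
        assert np.mean(fracs) == pytest.approx(0.01, abs=0.003)


def _brute_force_cluster_p(Y, X, c_idx, mask_shape, p_form):
    """Enumeration oracle: per-permutation OLS by lstsq at every voxel,
    max 18-connected suprathreshold extent, exact p per observed cluster."""
    n, p = X.shape
    df = n - p
    t_crit = stats.t.isf(p_form, df)
    c = np.zeros(p)
    c[c_idx] = 1.0
    XtX_inv = np.linalg.inv(X.T @ X)

    def tmap(Yp):
        beta, *_ = np.linalg.lstsq(X, Yp, rcond=None)
        rss = ((Yp - X @ beta) ** 2).sum(axis=0)
        se = np.sqrt(rss / df * (c @ XtX_inv @ c))
        return (c @ beta) / se

    def max_extent(tv):
        supra = (tv >= t_crit).reshape(mask_shape)
        lab, nlab = ndimage.label(supra, structure=CONNECTIVITY_18)
        return 0 if nlab == 0 else np.bincount(lab.ravel())[1:].max()

    # observed clusters
    supra = (tmap(Y) >= t_crit).reshape(mask_shape)
    lab, nlab = ndimage.label(supra, structure=CONNECTIVITY_18)
    obs_extents = sorted(np.bincount(lab.ravel())[1:], reverse=True)

    # Freedman-Lane: permute reduced-model residuals
    Z = np.delete(X, c_idx, axis=1)
    Qz, _ = np.linalg.qr(Z)
    E = Y - Qz @ (Qz.T @ Y)
    null = [
        max_extent(tmap(E[list(perm)]))
        for perm in itertools.permutations(range(n))
    ]
    null = np.array(null)
    return obs_extents, [float((null >= e).mean()) for e in obs_extents]


class TestClusterFWE:
    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        n, shape = 6, (4, 4, 2)
        V = int(np.prod(shape))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, V)) + 0.8 * np.outer(X[:, 1], rng.random(V))
        con = ContrastSpec(np.array([0.0, 1.0]), "positive")
        res = cluster_fwe(
            Y, X, con, np.ones(shape, bool), p_form=0.05, exhaustive=True,
            n_perm=1,
        )
        obs_extents, p_oracle = _brute_force_cluster_p(Y, X, 1, shape, 0.05)
        assert sorted(res.table.extent_voxels, reverse=True) == obs_extents
        got = res.table.sort_values("extent_voxels", ascending=False).p_fwe.tolist()
        np.testing.assert_allclose(got, p_oracle, atol=1e-12)

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(22)
        n, shape = 6, (4, 4, 2)
        V = int(np.prod(shape))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Y = rng.standard_normal((n, V)) + 0.8 * np.outer(X[:, 1], rng.random(V))
        con = ContrastSpec(np.array([0.0, 1.0]), "positive")
        mask = np.ones(shape, bool)
        exh = cluster_fwe(Y, X, con, mask, p_form=0.05, exhaustive=True, n_perm=1)
        # n_perm >= n! auto-switches to enumeration: identical output
        auto = cluster_fwe(Y, X, con, mask, p_form=0.05, n_perm=720)
        pd.testing.assert_frame_equal(exh.table, auto.table)
        sampled = cluster_fwe(Y, X, con, mask, p_form=0.05, n_perm=600, seed=5)
        np.testing.assert_allclose(
            sampled.table.p_fwe, exh.table.p_fwe, atol=0.07
        )

    def test_planted_effect_detected_in_correct_tail_only(self):
        rng = np.random.default_rng(23)
        n, shape = 60, (10, 10, 10)
        V = int(np.prod(shape))
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, rng.standard_normal(n)])
        effect = np.zeros(shape)
        effect[4:7, 4:7, 4:7] = -0.8  # negative association block
        Y = rng.standard_normal((n, V)) + np.outer(x, effect.ravel())
        mask = np.ones(shape, bool)
        neg = cluster_fwe(
            Y, X, ContrastSpec(np.array([0, 1.0, 0]), "negative"), mask,
            p_form=0.01, n_perm=99, seed=3,
        )
        assert (neg.table.p_fwe <= 0.05).any()
        top = neg.table.iloc[0]
        assert effect[int(top.peak_i), int(top.peak_j), int(top.peak_k)] < 0
        pos = cluster_fwe(
            Y, X, ContrastSpec(np.array([0, 1.0, 0]), "positive"), mask,
            p_form=0.01, n_perm=99, seed=3,
        )
        assert not (pos.table.p_fwe <= 0.05).any()

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            cluster_fwe(
                np.zeros((10, 8)), np.ones((10, 1)),
                ContrastSpec(np.array([1.0]), "positive"),
                np.ones((8, 1, 1), bool), n_perm=0,
            )


class TestReportClusters:
    def _result(self, z_peak):
        shape = (8, 8, 8)
        t = np.zeros(shape)
        t[2:5, 2:5, 2] = 3.0
        t[3, 3, 2] = z_peak  # single local max inside the cluster
        stat = _statmap_from_t(t, df=10_000)  # z ~ t at huge df
        labels, extents, _ = form_clusters(stat, 0.01)
        table = pd.DataFrame(
            {
                "cluster": [1], "extent_voxels": [int(extents[0])],
                "p_fwe": [0.01], "peak_z": [float(np.nanmax(stat.z))],
                "peak_i": [3], "peak_j": [3], "peak_k": [2],
            }
        )
        return ClusterResult(
            stat=stat, labels=labels, table=table,
            null_max_extent=np.zeros(9, int), t_threshold=2.33,
        )

    def test_z_floor_excludes_weak_peaks(self):
        assert report_clusters(self._result(3.4)).empty
        rep = report_clusters(self._result(3.8))
        assert len(rep) == 1
        assert rep.peak_z.iloc[0] == pytest.approx(3.8, abs=0.01)

    def test_roi_annotation_and_mm_coordinates(self):
        masks = {"perirhinal": np.zeros((8, 8, 8), bool)}
        masks["perirhinal"][3, 3, 2] = True
        rep = report_clusters(self._result(4.0), masks, voxel_mm=4.0)
        assert rep.rois.iloc[0] == "perirhinal"
        assert (rep.x_mm.iloc[0], rep.y_mm.iloc[0], rep.z_mm.iloc[0]) == (12.0, 12.0, 8.0)

    def test_empty_table_empty_report(self):
        res = self._result(4.0)
        res.table = res.table.iloc[0:0]
        assert report_clusters(res).empty
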