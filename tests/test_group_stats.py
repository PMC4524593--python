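"""Group inference: t maps, robust regression, cluster thresholding, ROI tests."""

import numpy as np
import pytest
import statsmodels.api as sm

from boldmvpa.core import VoxelGrid
from boldmvpa.group_stats import (
    GroupMap,
    GroupStatsConfig,
    cluster_threshold,
    estimate_cluster_extent,
    huber_irls,
    onesample_t_map,
    robust_regress_map,
    roi_level_tests,
)
from boldmvpa.masks import random_roi_sets

GRID = VoxelGrid.centered((10, 10, 10))
MASK = np.zeros(GRID.dims, bool)
MASK.ravel()[:300] = True


class TestOnesampleTMap:
    def test_zero_variance_voxel_gets_sentinel(self):
        maps = [np.full(300, 0.0) for _ in range(5)]
        for m in maps:
            m[0] = 2.0  # same nonzero value in every subject: zero variance
        gm = onesample_t_map(maps, MASK, GRID)
        assert gm.n_zero_variance == 300
        assert gm.p[MASK][0] == 1.0

    def test_t_sign_matches_mean_sign(self, rng):
        maps = [rng.standard_normal(300) + 0.5 for _ in range(12)]
        gm = onesample_t_map(maps, MASK, GRID)
        means = np.mean(maps, axis=0)
        t = gm.stat[MASK]
        nz = np.abs(t) > 1e-12
        assert np.all(np.sign(t[nz]) == np.sign(means[nz]))

    def test_null_rejection_rate_near_alpha(self, rng):
        rates = []
        for _ in range(30):
            maps = [rng.standard_normal(300) for _ in range(10)]
            gm = onesample_t_map(maps, MASK, GRID)
            rates.append((gm.p[MASK] < 0.05).mean())
        mean = np.mean(rates)
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(mean - 0.05) < max(2 * se, 0.01)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            onesample_t_map([rng.standard_normal(300)] * 2, MASK, GRID)


class TestHuberIrls:
    def test_matches_reference_implementation(self, rng):
        """Dual route: vectorized IRLS vs statsmodels RLM per response."""
        n, p, V = 20, 4, 25
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        Y = X @ rng.standard_normal((p, V)) + rng.standard_normal((n, V))
        Y[0, :5] += 8.0  # outliers
        beta, se = huber_irls(X, Y)
        for v in range(V):
            fit = sm.RLM(Y[:, v], X, M=sm.robust.norms.HuberT(t=1.345)).fit(
                maxiter=100, tol=1e-10
            )
            assert np.allclose(beta[:, v], fit.params, atol=1e-4)
            assert np.allclose(se[:, v], fit.bse, rtol=1e-3)

    def test_collinear_design_rejected(self, rng):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="collinear"):
            huber_irls(X, rng.standard_normal((10, 3)))


class TestRobustRegressMap:
    def _covs(self, rng, n):
        return {
            "age": rng.normal(34, 11, n),
            "depression": (rng.random(n) < 0.44).astype(float),
            "substance_use": (rng.random(n) < 0.25).astype(float),
        }

    def test_slope_recovery_within_ten_percent(self, rng):
        n, beta = 16, 0.04
        sev = rng.normal(60, 13, n)
        maps = [beta * s + 0.2 * rng.standard_normal(300) for s in sev]
        gm = robust_regress_map(maps, sev, self._covs(rng, n), MASK, GRID)
        est = gm.extra["slope"][MASK].mean()
        assert abs(est - beta) / beta < 0.10

    def test_severity_shift_leaves_slope_unchanged(self, rng):
        n = 12
        sev = rng.normal(60, 13, n)
        maps = [0.03 * s + 0.3 * rng.standard_normal(300) for s in sev]
        g1 = robust_regress_map(maps, sev, None, MASK, GRID)
        g2 = robust_regress_map(maps, sev + 1000.0, None, MASK, GRID)
        assert np.allclose(
            g1.extra["slope"][MASK], g2.extra["slope"][MASK], atol=1e-6
        )

    def test_zero_variance_maps_get_sentinel(self, rng):
        n = 10
        sev = rng.normal(60, 13, n)
        maps = [np.zeros(300) for _ in range(n)]
        gm = robust_regress_map(maps, sev, None, MASK, GRID)
        assert gm.n_zero_variance == 300
        assert np.all(gm.p[MASK] == 1.0)

    def test_too_few_subjects_rejected(self, rng):
        sev = np.arange(4.0)
        maps = [rng.standard_normal(300) for _ in range(4)]
        with pytest.raises(ValueError, match="at least"):
            robust_regress_map(maps, sev, self._covs(rng, 4), MASK, GRID)


def flood_fill_label(supra, connectivity):
    """Oracle: breadth-first flood fill over the chosen neighbourhood."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    labels = np.zeros(supra.shape, int)
    nxt = 0
    for idx in zip(*np.nonzero(supra)):
        if labels[idx]:
            continue
        nxt += 1
        stack = [idx]
        labels[idx] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < supra.shape[0]
                    and 0 <= nj < supra.shape[1]
                    and 0 <= nk < supra.shape[2]
                    and supra[ni, nj, nk]
                    and not labels[ni, nj, nk]
                ):
                    labels[ni, nj, nk] = nxt
                    stack.append((ni, nj, nk))
    return labels


def _pmap_from_blob(blob):
    p = np.ones(GRID.dims)
    p[blob] = 0.001
    return GroupMap(stat=np.where(blob, 5.0, 0.0), p=p,
                    mask=np.ones(GRID.dims, bool), grid=GRID)


class TestClusterThreshold:
    def test_blob_above_extent_survives(self):
        blob = np.zeros(GRID.dims, bool)
        blob[1:6, 1:6, 1:3] = True  # 50 voxels
        out = cluster_threshold(_pmap_from_blob(blob), GroupStatsConfig(min_cluster_extent=47))
        assert len(out.clusters) == 1
        assert out.clusters[0]["size"] == 50

    def test_blob_below_extent_removed(self):
        blob = np.zeros(GRID.dims, bool)
        blob[1:6, 1:5, 1:3] = True  # 40 voxels
        out = cluster_threshold(_pmap_from_blob(blob), GroupStatsConfig(min_cluster_extent=47))
        assert out.clusters == []
        assert not out.cluster_labels.any()

    def test_empty_suprathreshold_set(self):
        blob = np.zeros(GRID.dims, bool)
        out = cluster_threshold(_pmap_from_blob(blob), GroupStatsConfig())
        assert out.clusters == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_component_sizes_match_flood_fill_oracle(self, rng, connectivity):
        for _ in range(3):
            supra = rng.random(GRID.dims) < 0.2
            got = cluster_threshold(
                _pmap_from_blob(supra),
                GroupStatsConfig(min_cluster_extent=1, connectivity=connectivity),
            )
            oracle = flood_fill_label(supra, connectivity)
            got_sizes = sorted(c["size"] for c in got.clusters)
            oracle_sizes = sorted(np.bincount(oracle.ravel())[1:].tolist())
            assert got_sizes == oracle_sizes


class TestEstimateClusterExtent:
    def test_monotone_in_fwhm_and_small_for_white_noise(self):
        mask = np.ones(GRID.dims, bool)
        extents = [
            estimate_cluster_extent(mask, GRID, f, n_null_sims=150, seed=0)
            for f in (0.0, 6.0, 12.0)
        ]
        assert extents[0] <= 5
        assert extents[0] < extents[1] < extents[2]

    def test_nonincreasing_as_voxel_p_decreases(self):
        mask = np.ones(GRID.dims, bool)
        e_loose = estimate_cluster_extent(mask, GRID, 6.0, voxel_p=0.05, n_null_sims=150, seed=1)
        e_tight = estimate_cluster_extent(mask, GRID, 6.0, voxel_p=0.001, n_null_sims=150, seed=1)
        assert e_tight <= e_loose

    def test_deterministic_per_seed(self):
        mask = np.ones(GRID.dims, bool)
        a = estimate_cluster_extent(mask, GRID, 6.0, n_null_sims=120, seed=5)
        b = estimate_cluster_extent(mask, GRID, 6.0, n_null_sims=120, seed=5)
        assert a == b


class TestRoiLevelTests:
    def _roi_set(self):
        gm = np.zeros(GRID.dims, bool)
        gm[2:8, 2:8, 2:8] = True
        return random_roi_sets(GRID, gm, n_sets=1, n_rois=4, radius_mm=4.0, seed=0)[0]

    def test_all_zero_maps_flagged_degenerate(self):
        roi_set = self._roi_set()
        maps = [np.zeros(GRID.dims) for _ in range(8)]
        table = roi_level_tests(maps, roi_set)
        assert (table["flag"] == "degenerate").all()
        assert np.allclose(table["mean_weight"], 0.0)

    def test_empty_roi_flagged(self, rng):
        roi_set = self._roi_set()
        roi_set.rois["empty"] = np.zeros(GRID.dims, bool)
        maps = [rng.standard_normal(GRID.dims) for _ in range(8)]
        table = roi_level_tests(maps, roi_set).set_index("roi")
        assert table.loc["empty", "flag"] == "empty"

    def test_roi_mean_invariant_to_voxel_order(self, rng):
        roi_set = self._roi_set()
        maps = [rng.standard_normal(GRID.dims) for _ in range(6)]
        t1 = roi_level_tests(maps, roi_set)
        # permute the ROI dict order; per-ROI numbers must not change
        roi_set.rois = dict(reversed(list(roi_set.rois.items())))
        t2 = roi_level_tests(maps, roi_set)
        merged = t1.merge(t2, on="roi", suffixes=("_a", "_b"))
        assert np.allclose(merged["mean_weight_a"], merged["mean_weight_b"])

    def test_severity_slope_reported_per_roi(self, rng):
        roi_set = self._roi_set()
        n = 12
        sev = rng.normal(60, 13, n)
        maps = [0.02 * s + 0.1 * rng.standard_normal(GRID.dims) for s in sev]
        table = roi_level_tests(maps, roi_set, sev, None)
        assert np.all(np.isfinite(table["slope"]))
        assert np.allclose(table["slope"], 0.02, atol=0.01)
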