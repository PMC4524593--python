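"""Preprocessing stages: Volterra expansion, nuisance regression, smoothness
estimation, blur-to-FWHM, percent signal change, detrending."""


import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from boldmvpa.core import MotionParams, VoxelGrid
from boldmvpa.preprocess import (
    NuisanceMatrix,
    SmoothingConfig,
    assemble_nuisance,
    detrend,
    estimate_fwhm,
    preprocess_run,
    regress_nuisance,
    smooth_to_fwhm,
    to_psc,
    volterra_expand,
)

from conftest import make_run

GRID = VoxelGrid.centered((20, 20, 20))
FULL = np.ones(GRID.dims, dtype=bool)


def noise_run(rng, T=20, grid=GRID):
    return make_run(rng.standard_normal((*grid.dims, T)), grid)


class TestVolterra:
    def test_expansion_has_24_columns(self, rng):
        motion = MotionParams(rng.standard_normal((30, 6)))
        nm = volterra_expand(motion)
        assert nm.n_columns == 24

    def test_zero_motion_block_drops_to_empty(self):
        nm = volterra_expand(MotionParams(np.zeros((10, 6))))
        assert nm.n_columns == 0  # all-zero columns are dropped at assembly

    def test_hand_computed_terms_and_zero_lag_padding(self):
        motion = np.zeros((2, 6))
        motion[:, 0] = [1.0, 2.0]
        nm = volterra_expand(MotionParams(motion))
        cols = dict(zip(nm.labels, nm.matrix.T))
        assert np.array_equal(cols["trans_x"], [1.0, 2.0])
        assert np.array_equal(cols["trans_x_sq"], [1.0, 4.0])
        assert np.array_equal(cols["trans_x_lag"], [0.0, 1.0])
        # lagged R^2 = (0, 1) duplicates lagged R exactly and is dropped
        assert "trans_x_sq_lag" not in cols

    def test_single_tr_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            volterra_expand(MotionParams(np.ones((1, 6))))


class TestRegressNuisance:
    def _nuisance(self, rng, T):
        return NuisanceMatrix(rng.standard_normal((T, 3)), ["a", "b", "c"])

    def test_voxel_equal_to_regressor_gives_zero_residual(self, rng):
        T = 20
        nm = self._nuisance(rng, T)
        data = np.zeros((*GRID.dims, T))
        data[0, 0, 0] = nm.matrix[:, 1]
        run = make_run(data, GRID)
        out = regress_nuisance(run, nm, FULL)
        assert np.allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_orthogonal_nuisance_removes_only_mean(self, rng):
        T = 20
        x = rng.standard_normal(T)
        x -= x.mean()
        nm_cols = rng.standard_normal((T, 2))
        # orthogonalize nuisance against x and the constant
        for j in range(2):
            nm_cols[:, j] -= nm_cols[:, j].mean()
            nm_cols[:, j] -= x * (nm_cols[:, j] @ x) / (x @ x)
        nm = NuisanceMatrix(nm_cols, ["a", "b"])
        data = np.zeros((*GRID.dims, T))
        data[0, 0, 0] = x + 7.0
        out = regress_nuisance(make_run(data, GRID), nm, FULL)
        assert np.allclose(out.data[0, 0, 0], x, atol=1e-10)

    def test_residuals_orthogonal_to_every_regressor(self, rng):
        T = 30
        nm = self._nuisance(rng, T)
        run = noise_run(rng, T)
        out = regress_nuisance(run, nm, FULL)
        resid = out.data.reshape(-1, T)
        dots = np.abs(resid @ nm.matrix)
        assert dots.max() < 1e-6 * np.linalg.norm(run.data)

    def test_rank_deficient_design_rejected(self, rng):
        T = 20
        col = rng.standard_normal(T)
        mat = np.column_stack([col, 2 * col + 1e-18, rng.standard_normal(T)])
        nm = NuisanceMatrix(mat, ["a", "a2", "b"])
        with pytest.raises(ValueError, match="rank deficient"):
            regress_nuisance(noise_run(rng, T), nm, FULL)

    def test_assemble_nuisance_column_count(self, rng):
        run = noise_run(rng, 30)
        run = run.with_data(run.data + 100.0)
        wm = np.zeros(GRID.dims, bool)
        csf = np.zeros(GRID.dims, bool)
        wm[:3], csf[4:6] = True, True
        motion = MotionParams(np.cumsum(rng.standard_normal((30, 6)), axis=0) * 0.1)
        run.motion.values[:] = motion.values
        nm = assemble_nuisance(run, wm, csf, polyorder=2)
        # 24 Volterra + wm + csf + poly0..2
        assert nm.n_columns == 24 + 2 + 3


class TestEstimateFwhm:
    def test_white_noise_estimates_voxel_size(self, rng):
        run = noise_run(rng)
        assert abs(estimate_fwhm(run, FULL) - 3.0) / 3.0 < 0.20

    def test_presmoothed_noise_recovers_kernel_width(self, rng):
        sig = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        data = gaussian_filter(
            rng.standard_normal((*GRID.dims, 20)), sigma=(sig, sig, sig, 0)
        )
        est = estimate_fwhm(make_run(data, GRID), FULL)
        assert 5.0 <= est <= 7.0

    def test_spatially_constant_image_gives_sentinel(self):
        t = np.arange(5, dtype=float)
        data = np.broadcast_to(t, (*GRID.dims, 5)).copy()
        assert estimate_fwhm(make_run(data, GRID), FULL) == np.inf

    def test_single_tr_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_fwhm(noise_run(rng, T=1), FULL)


class TestSmoothToFwhm:
    def test_white_noise_reaches_target(self, rng):
        run = noise_run(rng)
        cfg = SmoothingConfig(target_fwhm_mm=8.0, tolerance_mm=0.5)
        out = smooth_to_fwhm(run, cfg, FULL)
        assert abs(estimate_fwhm(out, FULL) - 8.0) <= cfg.tolerance_mm

    def test_already_at_target_is_noop(self, rng):
        sig = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        data = gaussian_filter(
            rng.standard_normal((*GRID.dims, 10)), sigma=(sig, sig, sig, 0)
        )
        run = make_run(data, GRID)
        out = smooth_to_fwhm(run, SmoothingConfig(target_fwhm_mm=8.0, tolerance_mm=1.0), FULL)
        assert np.allclose(out.data, run.data)

    def test_oversmoothed_input_warns_and_passes_through(self, rng):
        sig = 12.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        data = gaussian_filter(
            rng.standard_normal((*GRID.dims, 10)), sigma=(sig, sig, sig, 0)
        )
        run = make_run(data, GRID)
        with pytest.warns(UserWarning, match="already smoother"):
            out = smooth_to_fwhm(run, SmoothingConfig(target_fwhm_mm=8.0), FULL)
        assert out.data is run.data

    def test_per_volume_mean_preserved(self, rng):
        run = noise_run(rng, T=5)
        run = run.with_data(run.data + 10.0)
        out = smooth_to_fwhm(run, SmoothingConfig(target_fwhm_mm=8.0), FULL)
        for t in range(5):
            before = run.data[..., t][FULL].mean()
            after = out.data[..., t][FULL].mean()
            assert abs(after - before) / abs(before) < 0.01


class TestToPsc:
    def test_constant_timeseries_becomes_zero(self):
        data = np.full((*GRID.dims, 6), 50.0)
        out = to_psc(make_run(data, GRID), FULL)
        assert np.allclose(out.data, 0.0)

    def test_hand_computed_example(self):
        data = np.full((*GRID.dims, 2), 100.0)
        data[0, 0, 0] = [90.0, 110.0]
        out = to_psc(make_run(data, GRID), FULL)
        assert np.allclose(out.data[0, 0, 0], [-10.0, 10.0])

    def test_output_temporal_mean_is_zero(self, rng):
        data = rng.standard_normal((*GRID.dims, 9)) + 100.0
        out = to_psc(make_run(data, GRID), FULL)
        assert np.abs(out.data.mean(axis=3)).max() < 1e-10

    def test_near_zero_mean_voxels_zeroed_with_warning(self, rng):
        data = rng.standard_normal((*GRID.dims, 8)) * 0.001 + 100.0
        data[0, 0, 0] = rng.standard_normal(8) * 0.001  # mean ~ 0
        with pytest.warns(UserWarning, match="near-zero baseline"):
            out = to_psc(make_run(data, GRID), FULL)
        assert np.allclose(out.data[0, 0, 0], 0.0)


class TestDetrend:
    def test_linear_ramp_removed_exactly(self):
        t = np.linspace(0, 1, 12)
        data = np.broadcast_to(3.0 * t + 1.0, (*GRID.dims, 12)).copy()
        out = detrend(make_run(data, GRID), polyorder=1)
        assert np.abs(out.data).max() < 1e-10

    def test_order_zero_is_mean_centering(self, rng):
        run = noise_run(rng, T=10)
        out = detrend(run, polyorder=0)
        assert np.allclose(out.data, run.data - run.data.mean(axis=3, keepdims=True))

    def test_residuals_orthogonal_to_polynomial_basis(self, rng):
        T = 15
        run = noise_run(rng, T)
        out = detrend(run, polyorder=3)
        t = np.linspace(-1, 1, T)
        basis = np.column_stack([t**d for d in range(4)])
        dots = np.abs(out.data.reshape(-1, T) @ basis)
        assert dots.max() < 1e-8 * np.linalg.norm(run.data)

    def test_idempotent(self, rng):
        run = noise_run(rng, T=15)
        once = detrend(run, polyorder=2)
        twice = detrend(once, polyorder=2)
        assert np.allclose(once.data, twice.data, atol=1e-8)


class TestPipeline:
    def test_session_anchoring_preserves_condition_contrast(self, preprocessed_subject, signal_subject):
        """Trauma-minus-neutral feature means track the planted pattern."""
        prep, truth = preprocessed_subject
        tr = np.mean([r.data.mean(axis=3) for r in prep.runs_for("trauma", 3)], axis=0)
        ne = np.mean([r.data.mean(axis=3) for r in prep.runs_for("neutral", 3)], axis=0)
        diff = (tr - ne)[truth.signal_mask]
        pat = truth.pattern.mean(axis=0)[truth.signal_mask]
        assert np.corrcoef(diff, pat)[0, 1] > 0.8

    def test_residuals_orthogonal_to_nuisance_after_pipeline(self, rng):
        from boldmvpa.simulate import SimConfig, generate_subject

        ds, _ = generate_subject(
            SimConfig(seed=3, grid_dims=(14, 14, 14), trs_per_run=30,
                      n_runs_per_condition=1, n_signal_voxels=20)
        )
        run = ds.runs[0]
        out = preprocess_run(run, ds.gm_mask, ds.wm_mask, ds.csf_mask, smoothing=None)
        nm = assemble_nuisance(run, ds.wm_mask, ds.csf_mask, polyorder=2)
        # motion columns of the original design stay orthogonal to residuals
        brain = ds.gm_mask | ds.wm_mask | ds.csf_mask
        resid = out.data[brain]  # (V, T); PSC-scaled residuals + offset=0 here
        motion_cols = nm.matrix[:, :24]
        dots = np.abs(resid @ motion_cols)
        assert dots.max() < 1e-5 * np.linalg.norm(resid)
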