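"""Synthetic BOLD data with known discriminative structure.

The generator emulates the design of a script-driven memory-recall study:
each subject contributes five repetitions of a ~3-minute task run per
condition (two conditions, TR = 2 s, 3-mm isotropic grid).  One condition
("trauma") carries an additive, spatially smoothed multivoxel activation
pattern on a known set of grey-matter voxels; the other ("neutral") does not.
Every run further contains AR(1) temporal noise, slow polynomial drift,
compartment-wide WM/CSF nuisance signals, and rigid-body motion simulated as
a weakly mean-reverting random walk.  Optional non-stationarity partially
re-draws the signal support between successive repetitions, emulating the
drifting network configuration seen under repeated recall of the same memory.

The anatomical phantom is a concentric-shell "brain": a CSF core, a WM shell
and an outer GM shell on a small centred grid, so that the full pipeline runs
at desk scale while exercising every code path of the real-size analysis.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .core import NEUTRAL, TRAUMA, BoldRun, MotionParams, SubjectDataset, VoxelGrid

__all__ = [
    "SimConfig",
    "GroundTruth",
    "phantom_tissue_masks",
    "generate_motion",
    "generate_subject",
    "generate_cohort",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Phantom shell radii in mm (CSF core < WM shell < GM shell), scaled to the
# default 24-voxel / 3-mm grid.  Chosen so the GM shell holds a few thousand
# voxels -- large enough for whole-"brain" decoding, small enough for tests.
_R_CSF = 9.0
_R_WM = 20.0
_R_GM = 33.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design being emulated: 5 repetitions per
    condition of 90 TRs (3 min at TR = 2 s) on a 3-mm isotropic grid.

    Parameters
    ----------
    n_runs_per_condition : int
        Repetitions of each condition (default 5).
    trs_per_run : int
        Volumes per run (default 90 = 3 min at TR 2 s; rest periods are not
        simulated because they are excluded from classification anyway).
    effect_size : float
        Mean trauma-vs-neutral separation per signal voxel, in units of the
        noise SD (RMS amplitude of the discriminative pattern over its
        support).
    n_signal_voxels : int
        Size of the signal support within GM.  The default covers roughly a
        quarter of the default phantom's GM: recall engages a brain-wide
        distributed state, and a kernel classifier over thousands of voxels
        can only see a signal whose squared norm is commensurate with the
        feature count.
    signal_fwhm_mm : float
        FWHM of the spatial smoothing applied to the signed pattern before
        rescaling, giving spatially coherent (not salt-and-pepper) signal.
    ar1_coef : float in [0, 1)
        Lag-1 temporal autocorrelation of the voxel noise.
    drift_amplitude : float
        SD of the random low-order polynomial drift, in noise-SD units.
    motion_step_sd : float
        Per-TR step SD of the motion random walk (mm / degrees).
    noise_fwhm_mm : float
        Intrinsic spatial smoothness (FWHM) of the voxel noise.  EPI noise
        is spatially correlated; white voxel noise is both unrealistic and
        pathological for TR-level decoding (run-wise detrending then makes
        same-run volumes systematically dissimilar in a way a powerful
        classifier exploits).
    envelope_amplitude : float
        Optional engagement fluctuation: with a nonzero amplitude the
        condition signal is modulated by a two-state Markov envelope
        (vivid-recall episodes at ``1 + amplitude`` vs lulls at
        ``1 - amplitude``, episode occupancy ``envelope_p_high``, mean dwell
        ``envelope_dwell_trs`` TRs).  The default 0 models sustained
        engagement throughout the narrated recall.
    nonstationarity : float in [0, 1]
        Fraction of the signal support re-drawn between successive
        repetitions of the trauma condition.
    severity_coupling : float
        Cohort-level scaling of the signal amplitude inside a designated
        coupling ROI by the standardized symptom-severity covariate.
    motion_artifact : float
        Gain of a motion-coupled artifact: standardized framewise
        displacement times a spatially smooth random gain map (motion
        artifacts are spatially heterogeneous; a spatially uniform one would
        be absorbed by the WM/CSF mean regressors).  0 disables it, which is
        the study condition (decoding should not be driven by motion).
    noise_sd, baseline : float
        Stationary noise SD and additive baseline level.  The baseline of
        1000 arbitrary units keeps percent-signal-change well defined.
    grid_dims : tuple of int
        Phantom grid size (default 24^3 at 3 mm: a desk-scale brain).
    """

    n_runs_per_condition: int = 5
    trs_per_run: int = 90
    tr_seconds: float = 2.0
    effect_size: float = 1.5
    n_signal_voxels: int = 1100
    signal_fwhm_mm: float = 6.0
    ar1_coef: float = 0.35
    noise_fwhm_mm: float = 6.0
    envelope_amplitude: float = 0.0
    envelope_p_high: float = 0.4
    envelope_dwell_trs: float = 10.0
    drift_amplitude: float = 2.0
    motion_step_sd: float = 0.02
    nonstationarity: float = 0.0
    severity_coupling: float = 0.0
    seed: int = 0
    noise_sd: float = 1.0
    baseline: float = 1000.0
    voxel_size_mm: float = 3.0
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    motion_artifact: float = 0.0

    def __post_init__(self) -> None:
        if self.n_runs_per_condition < 1:
            raise ValueError("n_runs_per_condition must be >= 1")
        if self.trs_per_run < 2:
            raise ValueError("trs_per_run must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.n_signal_voxels < 0:
            raise ValueError("n_signal_voxels must be nonnegative")
        if self.signal_fwhm_mm < 0:
            raise ValueError("signal_fwhm_mm must be nonnegative")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be nonnegative")
        if self.motion_step_sd < 0:
            raise ValueError("motion_step_sd must be nonnegative")
        if self.noise_fwhm_mm < 0:
            raise ValueError("noise_fwhm_mm must be nonnegative")
        if self.envelope_amplitude < 0:
            raise ValueError("envelope_amplitude must be nonnegative")
        if not 0 < self.envelope_p_high < 1:
            raise ValueError("envelope_p_high must lie in (0, 1)")
        if self.envelope_dwell_trs < 1:
            raise ValueError("envelope_dwell_trs must be >= 1")
        if not 0 <= self.nonstationarity <= 1:
            raise ValueError("nonstationarity must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.grid_dims, self.voxel_size_mm)


@dataclass
class GroundTruth:
    """What the generator actually planted, for validation downstream.

    Attributes
    ----------
    signal_mask : ndarray of bool
        Union over repetitions of the voxels carrying condition signal.
    pattern : ndarray, shape (n_reps, X, Y, Z)
        Signed signal amplitude per voxel for each trauma repetition
        (zero outside that repetition's support).
    severity_value : float
        The subject's severity covariate (NaN for standalone subjects).
    coupling_roi : ndarray of bool or None
        The designated ROI whose amplitude scales with severity, when
        cohort-level coupling is active.
    """

    signal_mask: np.ndarray
    pattern: np.ndarray
    severity_value: float = float("nan")
    coupling_roi: Optional[np.ndarray] = None


def phantom_tissue_masks(
    grid: VoxelGrid,
    r_csf: float = _R_CSF,
    r_wm: float = _R_WM,
    r_gm: float = _R_GM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concentric-shell GM / WM / CSF masks centred on the grid's mm origin.

    Radii scale with the grid's physical half-width so that non-default grid
    sizes still yield a proportionate brain.
    """
    scale = min(d * grid.voxel_size_mm for d in grid.dims) / 2.0 / 36.0
    if abs(scale - 1.0) > 0.25:  # keep defaults on near-default grids
        r_csf, r_wm, r_gm = r_csf * scale, r_wm * scale, r_gm * scale
    xx, yy, zz = grid.coordinate_volumes()
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    csf = r < r_csf
    wm = (r >= r_csf) & (r < r_wm)
    gm = (r >= r_wm) & (r <= r_gm)
    return gm, wm, csf


def generate_motion(T: int, step_sd: float, seed) -> MotionParams:
    """Six independent motion random walks with weak mean reversion.

    Each column is a cumulative sum of N(0, step_sd) steps with a mild decay
    (0.995 per TR) that keeps excursions bounded in expectation while leaving
    the step statistics essentially untouched.  Deterministic given `seed`
    (an int or a numpy Generator).
    """
    if T < 1:
        raise ValueError("T must be positive")
    if step_sd < 0:
        raise ValueError("step_sd must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    steps = rng.standard_normal((T, 6)) * step_sd
    # leaky integration: x_t = 0.995 x_{t-1} + step_t
    walks = lfilter([1.0], [1.0, -0.995], steps, axis=0)
    return MotionParams(walks)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], ar1: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_series, T), marginal SD = sd."""
    n, T = shape
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    e = rng.standard_normal((n, T)) * innov_sd
    # seed the recursion from the stationary distribution
    e[:, 0] = rng.standard_normal(n) * sd
    if ar1 == 0.0:
        return e
    return lfilter([1.0], [1.0, -ar1], e, axis=1)


def _legendre_basis(T: int, order: int) -> np.ndarray:
    """Columns: Legendre polynomials of degree 1..order on [-1, 1], unit SD."""
    t = np.linspace(-1.0, 1.0, T)
    cols = []
    for d in range(1, order + 1):
        c = np.zeros(d + 1)
        c[d] = 1.0
        col = np.polynomial.legendre.legval(t, c)
        cols.append(col / col.std())
    return np.column_stack(cols)


def _smooth_signed_pattern(
    support: np.ndarray,
    signs: np.ndarray,
    grid: VoxelGrid,
    fwhm_mm: float,
    rms_amplitude: float,
) -> np.ndarray:
    """Build a signed pattern volume: smooth the sign field, keep it on the
    support, rescale so its RMS over the support equals `rms_amplitude`."""
    vol = np.zeros(grid.dims)
    vol[support] = signs
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm
        vol = gaussian_filter(vol, sigma=sigma_vox)
    vol = np.where(support, vol, 0.0)
    rms = np.sqrt(np.mean(vol[support] ** 2)) if support.any() else 0.0
    if rms > 0:
        vol *= rms_amplitude / rms
    return vol


def _engagement_envelope(
    rng: np.random.Generator,
    T: int,
    amplitude: float,
    p_high: float,
    dwell_trs: float,
) -> np.ndarray:
    """Two-state Markov engagement envelope over one run.

    States are vivid-recall episodes (``1 + amplitude``) and lulls
    (``1 - amplitude``); the high state occupies fraction `p_high` of TRs
    in expectation and episodes persist for ``dwell_trs`` TRs on average.
    """
    if amplitude == 0.0:
        return np.ones(T)
    # leave probabilities chosen so the stationary occupancy is p_high
    leave_high = 1.0 / dwell_trs
    leave_low = leave_high * p_high / (1.0 - p_high)
    state = rng.random() < p_high
    env = np.empty(T)
    for t in range(T):
        env[t] = 1.0 + amplitude if state else 1.0 - amplitude
        u = rng.random()
        if state and u < leave_high:
            state = False
        elif not state and u < leave_low:
            state = True
    return env


def _draw_support(
    rng: np.random.Generator, gm_flat_idx: np.ndarray, n: int, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Draw n distinct flat voxel indices from GM, optionally excluding some."""
    pool = gm_flat_idx
    if exclude is not None and exclude.size:
        pool = np.setdiff1d(pool, exclude, assume_unique=False)
    return rng.choice(pool, size=n, replace=False)


def generate_subject(
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    severity_value: float = float("nan"),
    coupling_roi: np.ndarray | None = None,
    coupling_amplitude: float = 0.0,
    subject_id: str = "sub-01",
    covariates: dict | None = None,
) -> tuple[SubjectDataset, GroundTruth]:
    """Generate one subject: 2 x n_runs_per_condition runs plus ground truth.

    Trauma runs carry the additive smoothed pattern on the signal support;
    neutral runs do not.  With ``nonstationarity = q``, a fraction q of the
    support is re-drawn between successive trauma repetitions.  When
    `coupling_roi` is given, its GM voxels carry an extra positive-signed
    signal of amplitude `coupling_amplitude` (used by :func:`generate_cohort`
    to couple signal strength to symptom severity).
    """
    grid = config.grid()
    gm, wm, csf = phantom_tissue_masks(grid)
    n_gm = int(gm.sum())
    if config.n_signal_voxels > n_gm:
        raise ValueError(
            f"n_signal_voxels={config.n_signal_voxels} exceeds GM voxel count {n_gm}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    brain = gm | wm | csf
    brain_idx = np.flatnonzero(brain.ravel())
    gm_flat_idx = np.flatnonzero(gm.ravel())
    T = config.trs_per_run
    n_reps = config.n_runs_per_condition

    # --- per-repetition signal patterns -----------------------------------
    support = _draw_support(rng, gm_flat_idx, config.n_signal_voxels)
    signs = rng.choice([-1.0, 1.0], size=config.n_signal_voxels)
    patterns = np.zeros((n_reps, *grid.dims))
    supports = []
    for rep in range(n_reps):
        if rep > 0 and config.nonstationarity > 0 and config.n_signal_voxels > 0:
            n_redraw = int(round(config.nonstationarity * config.n_signal_voxels))
            if n_redraw > 0:
                keep = rng.permutation(config.n_signal_voxels)[n_redraw:]
                # redrawn voxels move to fresh GM locations
                new_vox = _draw_support(rng, gm_flat_idx, n_redraw, exclude=support)
                support = np.concatenate([support[keep], new_vox])
                signs = np.concatenate(
                    [signs[keep], rng.choice([-1.0, 1.0], size=n_redraw)]
                )
        sup_mask = np.zeros(grid.n_voxels, dtype=bool)
        sup_mask[support] = True
        sup_mask = sup_mask.reshape(grid.dims)
        supports.append(sup_mask)
        patterns[rep] = _smooth_signed_pattern(
            sup_mask, signs, grid, config.signal_fwhm_mm,
            config.effect_size * config.noise_sd,
        )
        if coupling_roi is not None and coupling_amplitude != 0.0:
            roi_gm = coupling_roi & gm
            patterns[rep][roi_gm] += coupling_amplitude * config.noise_sd

    union_mask = np.any(supports, axis=0)
    if coupling_roi is not None and coupling_amplitude != 0.0:
        union_mask = union_mask | (coupling_roi & gm)

    # --- noise, two passes --------------------------------------------------
    # Pass 1 draws every run's spatially correlated AR(1) noise; the
    # renormalization back to noise_sd uses per-voxel SDs pooled over *all*
    # runs.  A per-run renormalization would tie the volumes of a run
    # together (a run fingerprint a powerful classifier can exploit);
    # pooling keeps runs statistically exchangeable.
    drift_basis = _legendre_basis(T, order=2)
    noise_sigma_vox = (
        config.noise_fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm
        if config.noise_fwhm_mm > 0
        else 0.0
    )
    run_specs = [
        (condition, rep)
        for condition in (NEUTRAL, TRAUMA)
        for rep in range(1, n_reps + 1)
    ]
    noises = []
    for _ in run_specs:
        noise = _ar1_noise(rng, (brain_idx.size, T), config.ar1_coef, config.noise_sd)
        if noise_sigma_vox > 0:
            vol = np.zeros((*grid.dims, T))
            vol.reshape(-1, T)[brain_idx] = noise
            vol = gaussian_filter(vol, sigma=(noise_sigma_vox,) * 3 + (0.0,))
            noise = vol.reshape(-1, T)[brain_idx]
        noises.append(noise)
    pooled_sd = np.sqrt(
        np.mean([n.var(axis=1) for n in noises], axis=0)
    )[:, None]
    scale = config.noise_sd / np.where(pooled_sd > 1e-12, pooled_sd, 1.0)

    artifact_gain = None
    if config.motion_artifact != 0.0:
        # per-subject artifact topography (smooth, zero mean, unit SD):
        # motion artifact geometry is anatomically fixed across runs
        gain = np.zeros(grid.dims)
        gain[brain] = rng.standard_normal(brain_idx.size)
        if noise_sigma_vox > 0:
            gain = gaussian_filter(gain, sigma=noise_sigma_vox)
        g = gain.ravel()[brain_idx]
        artifact_gain = (g - g.mean()) / (g.std() + 1e-12)

    runs: list[BoldRun] = []
    for (condition, rep), noise in zip(run_specs, noises):
        data_flat = noise * scale
        # slow drift: random coefficients per voxel on Legendre 1..2
        coefs = rng.standard_normal((brain_idx.size, drift_basis.shape[1]))
        data_flat += (coefs @ drift_basis.T) * (
            config.drift_amplitude * config.noise_sd / np.sqrt(drift_basis.shape[1])
        )
        data_flat += config.baseline

        # compartment-wide nuisance timecourses in WM and CSF
        for comp_mask in (wm, csf):
            comp_sig = _ar1_noise(rng, (1, T), 0.9, config.noise_sd)[0]
            in_comp = comp_mask.ravel()[brain_idx]
            data_flat[in_comp] += comp_sig

        motion = generate_motion(T, config.motion_step_sd, rng)
        if artifact_gain is not None:
            fd = np.abs(np.diff(motion.values, axis=0, prepend=motion.values[:1])).sum(axis=1)
            fd_z = (fd - fd.mean()) / (fd.std() + 1e-12)
            data_flat += (
                config.motion_artifact * config.noise_sd
                * artifact_gain[:, None] * fd_z[None, :]
            )

        if condition == TRAUMA:
            envelope = _engagement_envelope(
                rng, T, config.envelope_amplitude,
                config.envelope_p_high, config.envelope_dwell_trs,
            )
            pat_flat = patterns[rep - 1].ravel()[brain_idx]
            data_flat += pat_flat[:, None] * envelope[None, :]

        data = np.zeros((*grid.dims, T))
        data.reshape(-1, T)[brain_idx] = data_flat
        runs.append(
            BoldRun(
                data=data,
                grid=grid,
                tr_seconds=config.tr_seconds,
                condition=condition,
                repetition=rep,
                motion=motion,
            )
        )

    covs = {"severity": severity_value, "age": float("nan"),
            "depression": 0.0, "substance_use": 0.0}
    if covariates:
        covs.update(covariates)
    dataset = SubjectDataset(
        runs=runs, gm_mask=gm, wm_mask=wm, csf_mask=csf,
        covariates=covs, subject_id=subject_id,
    )
    truth = GroundTruth(
        signal_mask=union_mask,
        pattern=patterns,
        severity_value=severity_value,
        coupling_roi=coupling_roi,
    )
    return dataset, truth


COUPLING_ROI_RADIUS_MM = 6.0


def coupling_roi_center_mm(grid: VoxelGrid) -> tuple[float, float, float]:
    """mm centre of the severity-coupling ROI: mid-GM-shell on the +y axis,
    scaled with the phantom the way :func:`phantom_tissue_masks` scales."""
    scale = min(d * grid.voxel_size_mm for d in grid.dims) / 2.0 / 36.0
    if abs(scale - 1.0) <= 0.25:
        scale = 1.0
    return (0.0, (_R_WM + _R_GM) / 2.0 * scale, 0.0)

# Cohort covariate distributions: PCL-like severity and demographics matched
# to the clinical sample being emulated (severity ~ N(62, 13.5) clipped to the
# instrument's 17-85 range; age ~ N(34, 11); comorbidity rates 44% / 25%).
_SEVERITY_MEAN, _SEVERITY_SD = 62.3, 13.5
_AGE_MEAN, _AGE_SD = 33.8, 10.8
_P_DEPRESSION, _P_SUBSTANCE = 0.44, 0.25


def generate_cohort(
    n_subjects: int, config: SimConfig
) -> list[tuple[SubjectDataset, GroundTruth]]:
    """Generate a cohort with severity-coupled signal in a designated ROI.

    Severity covariates are drawn from the PCL-like distribution above; the
    signal amplitude inside the coupling ROI is
    ``severity_coupling * standardized severity`` (plus the base pattern where
    it overlaps).  Per-subject seeds derive from ``config.seed``.
    """
    if n_subjects < 2:
        raise ValueError("generate_cohort requires n_subjects >= 2")
    from .masks import sphere_mask  # local import to avoid a cycle

    grid = config.grid()
    roi = sphere_mask(coupling_roi_center_mm(grid), COUPLING_ROI_RADIUS_MM, grid)

    master = np.random.default_rng(config.seed)
    severity = np.clip(
        master.normal(_SEVERITY_MEAN, _SEVERITY_SD, n_subjects), 17.0, 85.0
    )
    age = np.clip(master.normal(_AGE_MEAN, _AGE_SD, n_subjects), 18.0, 65.0)
    depression = (master.random(n_subjects) < _P_DEPRESSION).astype(float)
    substance = (master.random(n_subjects) < _P_SUBSTANCE).astype(float)
    z_sev = (severity - severity.mean()) / severity.std()

    seeds = np.random.SeedSequence(config.seed).spawn(n_subjects)
    cohort = []
    for i in range(n_subjects):
        rng = np.random.default_rng(seeds[i])
        coupling_amp = config.severity_coupling * z_sev[i]
        ds, truth = generate_subject(
            config,
            rng=rng,
            severity_value=float(severity[i]),
            coupling_roi=roi if config.severity_coupling != 0.0 else None,
            coupling_amplitude=coupling_amp,
            subject_id=f"sub-{i + 1:02d}",
            covariates={
                "severity": float(severity[i]),
                "age": float(age[i]),
                "depression": float(depression[i]),
                "substance_use": float(substance[i]),
            },
        )
        cohort.append((ds, truth))
    return cohort
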