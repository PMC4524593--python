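"""Preprocessing of BOLD runs: nuisance regression, smoothing, detrending, PSC.

The stages mirror a standard task-fMRI stream on already-aligned data:

1. nuisance regression against the 24-term Volterra expansion of the six
   rigid-body motion parameters plus mean WM and CSF signals,
2. optional iterative spatial smoothing to a target FWHM (the estimate-and-add
   scheme of blur-to-FWHM tools),
3. polynomial detrending,
4. rescaling to percent signal change (PSC).

The single entry point :func:`preprocess_run` applies the stages in that
order, so methodological permutations differ only in the smoothing flag.
Because nuisance regression and detrending remove each voxel's temporal mean,
the entry point computes PSC against the voxel's *pre-regression* baseline
mean; the standalone :func:`to_psc` uses the timeseries' own mean, per its
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BoldRun, MotionParams

__all__ = [
    "NuisanceMatrix",
    "SmoothingConfig",
    "volterra_expand",
    "assemble_nuisance",
    "regress_nuisance",
    "estimate_fwhm",
    "smooth_to_fwhm",
    "to_psc",
    "detrend",
    "preprocess_run",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class NuisanceMatrix:
    """A T x K nuisance design with labelled columns.

    Exact-duplicate and all-zero columns are dropped at assembly (an all-zero
    motion table, say, contributes nothing); rank deficiency after that drop
    is reported by :func:`regress_nuisance`.
    """

    def __init__(self, matrix: np.ndarray, labels: list[str]):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError("nuisance matrix must be 2-D")
        if matrix.shape[1] != len(labels):
            raise ValueError("label count must match column count")
        keep: list[int] = []
        seen: list[np.ndarray] = []
        for j in range(matrix.shape[1]):
            col = matrix[:, j]
            if np.allclose(col, 0.0):
                continue
            if any(np.array_equal(col, s) for s in seen):
                continue
            seen.append(col)
            keep.append(j)
        self.matrix = matrix[:, keep]
        self.labels = [labels[j] for j in keep]

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self):
        """Labelled DataFrame view, handy for TSV audit output."""
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.labels)


@dataclass(frozen=True)
class SmoothingConfig:
    """Iterative blur-to-FWHM settings (target in mm of *final* smoothness)."""

    enabled: bool = True
    target_fwhm_mm: float = 8.0
    max_iterations: int = 5
    tolerance_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.target_fwhm_mm <= 0:
            raise ValueError("target_fwhm_mm must be positive")
        if self.tolerance_mm <= 0:
            raise ValueError("tolerance_mm must be positive")


def volterra_expand(motion: MotionParams) -> NuisanceMatrix:
    """24 motion regressors: [R, R^2, R lagged one TR, R^2 lagged one TR].

    The lagged terms are zero-padded at t = 0 (no predecessor), which keeps
    the first TR in the design and label alignment trivial.
    """
    R = motion.values
    if R.shape[0] < 2:
        raise ValueError("Volterra expansion requires at least 2 TRs")
    R2 = R**2
    lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    lag2 = np.vstack([np.zeros((1, 6)), R2[:-1]])
    mat = np.hstack([R, R2, lag, lag2])
    names = list(MotionParams.COLUMNS)
    labels = (
        [f"{n}" for n in names]
        + [f"{n}_sq" for n in names]
        + [f"{n}_lag" for n in names]
        + [f"{n}_sq_lag" for n in names]
    )
    return NuisanceMatrix(mat, labels)


def assemble_nuisance(
    run: BoldRun,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    polyorder: int = 0,
) -> NuisanceMatrix:
    """Full nuisance design: 24 Volterra motion terms + WM mean + CSF mean
    + polynomial trend columns of degree 0..polyorder.

    Drift terms belong *in* the nuisance fit: regressing stochastic smooth
    regressors (motion walks, WM/CSF means) against data that still contain
    drift transfers a copy of those run-specific timecourses into every
    voxel (the fitted slope picks up the drift-regressor correlation), which
    a later detrend cannot undo.  Joint estimation makes the motion/WM/CSF
    coefficients partial ones and avoids that artifact.
    """
    vol = volterra_expand(run.motion)
    T = run.n_trs
    flat = run.data.reshape(-1, T)
    wm = flat[np.asarray(wm_mask, dtype=bool).ravel()].mean(axis=0)
    csf = flat[np.asarray(csf_mask, dtype=bool).ravel()].mean(axis=0)
    t = np.linspace(-1.0, 1.0, T)
    poly = np.column_stack([t**d for d in range(polyorder + 1)])
    mat = np.hstack([vol.matrix, wm[:, None], csf[:, None], poly])
    labels = vol.labels + ["wm_mean", "csf_mean"] + [
        f"poly{d}" for d in range(polyorder + 1)
    ]
    return NuisanceMatrix(mat, labels)


def regress_nuisance(
    run: BoldRun, nuisance: NuisanceMatrix, mask: np.ndarray
) -> BoldRun:
    """Residualize every in-mask voxel against the nuisance columns + intercept.

    The residuals are orthogonal to every regressor (and mean-centred, since
    an intercept is always included).  Voxels outside `mask` are passed
    through unchanged.
    """
    if nuisance.n_trs != run.n_trs:
        raise ValueError("nuisance rows must equal the run's TR count")
    mask = np.asarray(mask, dtype=bool)
    T = run.n_trs
    X = nuisance.matrix
    if not any(np.allclose(X[:, j], X[0, j]) and X[0, j] != 0 for j in range(X.shape[1])):
        X = np.hstack([np.ones((T, 1)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"nuisance design is rank deficient ({rank} < {X.shape[1]} columns)"
        )
    flat = run.data.reshape(-1, T)
    Y = flat[mask.ravel()].T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = flat.copy()
    out[mask.ravel()] = resid.T
    return run.with_data(out.reshape(run.data.shape))


def estimate_fwhm(run: BoldRun, mask: np.ndarray) -> float:
    """Global spatial-smoothness estimate (FWHM, mm) of a run.

    Works on temporally differenced data (suppressing task structure), models
    the spatial autocorrelation at one voxel lag as a Gaussian, and combines
    the per-axis estimates geometrically.  Estimates below the voxel size are
    floored at the voxel size (the grid cannot resolve less); a spatially
    constant image returns ``inf`` (unbounded smoothness sentinel).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if run.n_trs < 2:
        raise ValueError("smoothness estimation requires at least 2 TRs")
    d = np.diff(run.data, axis=3)
    v = run.grid.voxel_size_mm
    fwhms = []
    total_var = d[mask].var()
    if total_var == 0.0:
        return float("inf")
    for axis in range(3):
        pair = mask & np.roll(mask, -1, axis=axis)
        # exclude wrap-around slice
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        pair[tuple(sl)] = False
        if not pair.any():
            continue
        a = d[pair]
        b = np.roll(d, -1, axis=axis)[pair]
        num = np.mean((a - b) ** 2)
        den = np.mean(a**2) + np.mean(b**2)
        if den == 0.0:
            return float("inf")
        rho = 1.0 - num / den
        if rho >= 1.0:
            return float("inf")
        if rho <= 0.0:
            fwhms.append(v)  # at or below the sampling limit
            continue
        fwhm = v * np.sqrt(2.0 * np.log(2.0) / (-np.log(rho)))
        fwhms.append(max(fwhm, v))
    if not fwhms:
        raise ValueError("mask has no neighbouring voxel pairs on any axis")
    return float(np.exp(np.mean(np.log(fwhms))))


def _masked_gaussian_smooth(
    vol: np.ndarray, mask: np.ndarray, sigma_vox: float
) -> np.ndarray:
    """Gaussian smoothing restricted to a mask, kernel renormalized inside it
    so the in-mask mean is preserved (no bleed-out at the mask edge)."""
    weights = gaussian_filter(mask.astype(float), sigma=sigma_vox)
    smoothed = gaussian_filter(np.where(mask, vol, 0.0), sigma=sigma_vox)
    out = vol.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out[mask] = (smoothed / np.where(weights > 1e-12, weights, 1.0))[mask]
    return out


def smooth_to_fwhm(
    run: BoldRun, cfg: SmoothingConfig, mask: np.ndarray
) -> BoldRun:
    """Iteratively smooth until the estimated FWHM reaches the target.

    Each iteration measures the current smoothness and applies the
    incremental Gaussian kernel ``sqrt(target^2 - current^2)`` (Gaussian
    widths add in quadrature).  Stops within ``tolerance_mm`` of the target
    or after ``max_iterations`` (with a warning); if the data are already
    smoother than the target, warns and returns the run unchanged.
    """
    if not cfg.enabled:
        return run
    mask = np.asarray(mask, dtype=bool)
    v = run.grid.voxel_size_mm
    if cfg.target_fwhm_mm <= v:
        raise ValueError("target FWHM must exceed the voxel size")
    data = run.data
    current = estimate_fwhm(run, mask)
    if current > cfg.target_fwhm_mm + cfg.tolerance_mm:
        warnings.warn(
            f"data already smoother ({current:.2f} mm) than target "
            f"{cfg.target_fwhm_mm} mm; returning unchanged", stacklevel=2
        )
        return run
    for _ in range(cfg.max_iterations):
        if abs(current - cfg.target_fwhm_mm) <= cfg.tolerance_mm:
            return run.with_data(data)
        inc2 = cfg.target_fwhm_mm**2 - min(current, cfg.target_fwhm_mm) ** 2
        if inc2 <= 0:
            return run.with_data(data)
        sigma_vox = np.sqrt(inc2) / _FWHM_PER_SIGMA / v
        new = np.empty_like(data)
        for t in range(data.shape[3]):
            new[..., t] = _masked_gaussian_smooth(data[..., t], mask, sigma_vox)
        data = new
        run = run.with_data(data)
        current = estimate_fwhm(run, mask)
    if abs(current - cfg.target_fwhm_mm) > cfg.tolerance_mm:
        warnings.warn(
            f"smoothing stopped at {current:.2f} mm after "
            f"{cfg.max_iterations} iterations (target {cfg.target_fwhm_mm} mm)",
            stacklevel=2,
        )
    return run


def to_psc(
    run: BoldRun,
    mask: np.ndarray,
    baseline: np.ndarray | None = None,
    rel_threshold: float = 0.01,
) -> BoldRun:
    """Rescale each in-mask voxel to percent signal change.

    ``psc_t = 100 * (x_t - m) / m`` with ``m`` the voxel's temporal mean, or
    the caller-supplied per-voxel `baseline` (used by the pipeline after
    mean-removing stages).  Voxels whose baseline magnitude falls below
    ``rel_threshold`` x (global in-mask mean baseline) are zeroed and counted
    in the returned run's log (a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    T = run.n_trs
    flat = run.data.reshape(-1, T)
    m = mask.ravel()
    x = flat[m]
    mean = x.mean(axis=1) if baseline is None else np.asarray(baseline, dtype=float).ravel()[m]
    global_mean = np.abs(mean).mean()
    bad = np.abs(mean) < rel_threshold * global_mean
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxels with near-zero baseline set to 0 in PSC",
            stacklevel=2,
        )
    safe = np.where(bad, 1.0, mean)
    if baseline is None:
        psc = 100.0 * (x - mean[:, None]) / safe[:, None]
    else:
        # data already mean-removed relative to the stored baseline
        psc = 100.0 * x / safe[:, None]
    psc[bad] = 0.0
    out = flat.copy()
    out[m] = psc
    return run.with_data(out.reshape(run.data.shape))


def detrend(run: BoldRun, polyorder: int, mask: np.ndarray | None = None) -> BoldRun:
    """Remove a least-squares polynomial of the stated order from each voxel.

    polyorder 0 is exact mean-centring.  Applied to all voxels unless a mask
    is given.
    """
    if polyorder < 0:
        raise ValueError("polyorder must be >= 0")
    T = run.n_trs
    if T <= polyorder:
        raise ValueError("need more TRs than polynomial order")
    t = np.linspace(-1.0, 1.0, T)
    X = np.column_stack([t**d for d in range(polyorder + 1)])
    flat = run.data.reshape(-1, T)
    if mask is None:
        Y = flat.T
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out = (Y - X @ beta).T
    else:
        m = np.asarray(mask, dtype=bool).ravel()
        out = flat.copy()
        Y = flat[m].T
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out[m] = (Y - X @ beta).T
    return run.with_data(out.reshape(run.data.shape))


def preprocess_run(
    run: BoldRun,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    smoothing: SmoothingConfig | None = None,
    detrend_order: int = 2,
    nuisance_polyorder: int = 2,
    session_baseline: np.ndarray | None = None,
) -> BoldRun:
    """Default preprocessing pipeline for one run.

    Order: nuisance regression (jointly with polynomial drift terms)
    -> (optional) smoothing -> detrend -> PSC.

    Baseline anchoring: the per-run stages (nuisance regression, detrend)
    necessarily remove each voxel's within-run mean, so percent signal
    change is computed against a caller-supplied per-voxel *session*
    baseline (the voxel's mean over all of the subject's runs) when given:
    the run's mean deviation from that baseline is smoothed alongside the
    data and re-added before scaling.  Without the anchor (single-run use)
    the run's own pre-regression mean serves as the baseline and the run
    mean deviation is zero by construction.  Anchoring at the session level
    is what keeps between-run (condition) mean differences in the features;
    a run-anchored PSC would zero every voxel's mean in every run and leave
    nothing for a TR-level classifier but within-run dynamics.
    """
    brain = (
        np.asarray(gm_mask, dtype=bool)
        | np.asarray(wm_mask, dtype=bool)
        | np.asarray(csf_mask, dtype=bool)
    )
    run_mean = run.data.mean(axis=3)
    baseline = run_mean if session_baseline is None else np.asarray(session_baseline)
    offset = run_mean - baseline  # the run's mean deviation from the anchor
    nuis = assemble_nuisance(run, wm_mask, csf_mask, polyorder=nuisance_polyorder)
    out = regress_nuisance(run, nuis, brain)
    if smoothing is not None and smoothing.enabled:
        # smooth the offset with the one-shot incremental kernel implied by
        # the pre-smoothing estimate, so both arms treat it consistently
        f0 = estimate_fwhm(out, brain)
        inc2 = smoothing.target_fwhm_mm**2 - min(f0, smoothing.target_fwhm_mm) ** 2
        if np.isfinite(f0) and inc2 > 0:
            sigma_vox = np.sqrt(inc2) / _FWHM_PER_SIGMA / run.grid.voxel_size_mm
            offset = _masked_gaussian_smooth(offset, brain, sigma_vox)
        out = smooth_to_fwhm(out, smoothing, brain)
    if detrend_order is not None:
        out = detrend(out, detrend_order, mask=brain)
    if session_baseline is not None:
        out = out.with_data(out.data + offset[..., None] * brain[..., None])
    out = to_psc(out, brain, baseline=baseline)
    return out
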