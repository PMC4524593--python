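"""Core containers: voxel grids, motion tables, BOLD runs and subject datasets.

These are thin, validated wrappers around numpy arrays.  A :class:`VoxelGrid`
defines the mapping between integer voxel indices and millimetre (MNI-style)
coordinates; a :class:`BoldRun` is one 4-D timeseries on such a grid together
with its acquisition metadata; a :class:`SubjectDataset` bundles the runs of
one subject with tissue masks and clinical covariates and is the unit on which
within-subject decoding operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "MotionParams",
    "BoldRun",
    "SubjectDataset",
    "TRAUMA",
    "NEUTRAL",
]

#: Canonical condition labels used throughout the pipeline.
TRAUMA = "trauma"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class VoxelGrid:
    """A regular isotropic voxel grid embedded in millimetre space.

    Voxel index ``(i, j, k)`` maps to the millimetre coordinate
    ``origin_mm + (i, j, k) * voxel_size_mm``; the mapping is invertible on
    the grid (nearest-voxel rounding is used for mm -> index).

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis.
    voxel_size_mm : float
        Isotropic voxel edge length in mm (default 3.0, a standard EPI
        resolution).
    origin_mm : tuple of float
        Millimetre coordinate of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @classmethod
    def centered(cls, dims: Sequence[int], voxel_size_mm: float = 3.0) -> "VoxelGrid":
        """Grid whose millimetre origin sits at the centre of the volume."""
        dims = tuple(int(d) for d in dims)
        origin = tuple(-(d - 1) / 2.0 * voxel_size_mm for d in dims)
        return cls(dims=dims, voxel_size_mm=voxel_size_mm, origin_mm=origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (RAS-style, diagonal)."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + index * self.voxel_size_mm

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates to the nearest integer voxel index."""
        mm = np.asarray(mm, dtype=float)
        idx = np.rint((mm - np.asarray(self.origin_mm)) / self.voxel_size_mm)
        return idx.astype(int)

    def contains_index(self, index: np.ndarray) -> np.ndarray:
        """Boolean: does each (..., 3) index lie inside the grid?"""
        index = np.asarray(index)
        return np.all((index >= 0) & (index < np.asarray(self.dims)), axis=-1)

    def coordinate_volumes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Three 3-D arrays giving the mm coordinate of every voxel centre."""
        axes = [
            self.origin_mm[a] + np.arange(self.dims[a]) * self.voxel_size_mm
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


class MotionParams:
    """A T x 6 table of rigid-body motion parameters, one row per TR.

    Columns are the three translations (mm) followed by the three rotations
    (degrees), the conventional realignment output.
    """

    COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 6:
            raise ValueError(
                f"motion table must have exactly 6 columns, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("motion table contains non-finite values")
        self.values = values

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, MotionParams) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotionParams(T={self.n_trs})"


@dataclass
class BoldRun:
    """One 4-D BOLD run: a (X, Y, Z, T) array on a grid, with metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel timeseries.  Must be finite everywhere.
    grid : VoxelGrid
    tr_seconds : float
        Repetition time in seconds.
    condition : str
        Task condition of the run (e.g. ``"trauma"`` or ``"neutral"``).
    repetition : int
        1-based repetition index of this condition's presentation.
    motion : MotionParams
        Per-TR rigid-body motion parameters; row count must equal T.
    """

    data: np.ndarray
    grid: VoxelGrid
    tr_seconds: float
    condition: str
    repetition: int
    motion: MotionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if self.data.shape[3] <= 0:
            raise ValueError("run must contain at least one TR")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains NaN or Inf")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.motion.n_trs != self.n_trs:
            raise ValueError(
                f"motion rows ({self.motion.n_trs}) != TR count ({self.n_trs})"
            )
        self.repetition = int(self.repetition)

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        """Copy of this run with `data` replaced, metadata preserved."""
        return BoldRun(
            data=data,
            grid=self.grid,
            tr_seconds=self.tr_seconds,
            condition=self.condition,
            repetition=self.repetition,
            motion=self.motion,
        )


@dataclass
class SubjectDataset:
    """All runs of one subject plus tissue masks and clinical covariates.

    Invariants enforced at construction: all runs share one grid and TR, the
    three tissue masks are pairwise disjoint boolean volumes on that grid, and
    at least one run exists per condition.
    """

    runs: list[BoldRun]
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    covariates: Mapping[str, float] = field(default_factory=dict)
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("dataset must contain at least one run")
        grid = self.runs[0].grid
        tr = self.runs[0].tr_seconds
        for run in self.runs:
            if run.grid != grid:
                raise ValueError("all runs must share one voxel grid")
            if run.tr_seconds != tr:
                raise ValueError("all runs must share one TR")
        for name in ("gm_mask", "wm_mask", "csf_mask"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != grid.dims:
                raise ValueError(f"{name} shape {mask.shape} != grid dims {grid.dims}")
            setattr(self, name, mask)
        if (
            np.any(self.gm_mask & self.wm_mask)
            or np.any(self.gm_mask & self.csf_mask)
            or np.any(self.wm_mask & self.csf_mask)
        ):
            raise ValueError("tissue masks must be pairwise disjoint")
        if len(self.conditions) < 1:
            raise ValueError("dataset must contain at least one condition")

    @property
    def grid(self) -> VoxelGrid:
        return self.runs[0].grid

    @property
    def tr_seconds(self) -> float:
        return self.runs[0].tr_seconds

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels, in order of first appearance."""
        seen: list[str] = []
        for run in self.runs:
            if run.condition not in seen:
                seen.append(run.condition)
        return seen

    def runs_for(self, condition: str, k_runs: int | None = None) -> list[BoldRun]:
        """The first `k_runs` repetitions of `condition`, ordered by repetition."""
        runs = sorted(
            (r for r in self.runs if r.condition == condition),
            key=lambda r: r.repetition,
        )
        if k_runs is not None:
            if not 1 <= k_runs <= len(runs):
                raise ValueError(
                    f"k_runs={k_runs} outside 1..{len(runs)} for condition {condition!r}"
                )
            runs = runs[:k_runs]
        return runs

    def map_runs(self, fn) -> "SubjectDataset":
        """Apply ``fn(run) -> run`` to every run, returning a new dataset."""
        return SubjectDataset(
            runs=[fn(r) for r in self.runs],
            gm_mask=self.gm_mask,
            wm_mask=self.wm_mask,
            csf_mask=self.csf_mask,
            covariates=dict(self.covariates),
            subject_id=self.subject_id,
        )
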