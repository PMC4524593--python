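"""Voxel-selection masks: spheres at MNI coordinates, GM complements, random ROI sets.

The decoding experiments compare four voxel selections: the whole grey-matter
mask, eight 6-mm spheres at meta-analytic coordinates of the PTSD
neurocircuitry (amygdalohippocampal junction, hippocampi, ACC subdivisions,
retrosplenial/posterior-midline regions), the GM mask minus those spheres,
and sets of randomly placed spheres of the same number and radius.

Sphere membership uses the inclusive boundary (centre-to-centre distance
<= radius) after snapping the requested centre to the nearest voxel centre;
on a 3-mm isotropic grid a 6-mm sphere then contains exactly 33 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core import VoxelGrid

__all__ = [
    "ROISpec",
    "MaskSet",
    "PTSD_ROI_SPECS",
    "sphere_mask",
    "ptsd_roi_set",
    "random_roi_sets",
    "mask_complement",
    "group_gm_mask",
]


@dataclass(frozen=True)
class ROISpec:
    """A named spherical ROI: centre in MNI mm and radius in mm."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")


#: 6-mm spheres at meta-analytic centres of the PTSD neurocircuitry (MNI mm).
PTSD_ROI_SPECS: tuple[ROISpec, ...] = (
    ROISpec("l_amygdalohippocampal", (-20.0, -8.0, -16.0)),
    ROISpec("l_hippocampus", (-32.0, -20.0, -8.0)),
    ROISpec("r_hippocampus", (28.0, -12.0, -24.0)),
    ROISpec("perigenual_acc", (-10.0, 24.0, 22.0)),
    ROISpec("dorsal_acc", (3.0, 26.0, 21.0)),
    ROISpec("retrosplenial", (0.0, -53.0, 8.0)),
    ROISpec("pcc", (2.0, -50.0, 22.0)),
    ROISpec("precuneus", (-1.0, -56.0, 35.0)),
)


@dataclass
class MaskSet:
    """A named collection of voxel masks on one grid.

    `rois` maps ROI name -> boolean volume.  `flagged` lists ROIs that ended
    up empty after GM intersection (kept, but flagged for the caller).
    """

    name: str
    grid: VoxelGrid
    rois: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = ""
    flagged: list[str] = field(default_factory=list)

    def union(self) -> np.ndarray:
        """Boolean volume: union of all ROIs (de-duplicated by construction)."""
        out = np.zeros(self.grid.dims, dtype=bool)
        for m in self.rois.values():
            out |= m
        return out

    def voxel_counts(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.rois.items()}

    @property
    def n_total_voxels(self) -> int:
        return int(self.union().sum())

    def __len__(self) -> int:
        return len(self.rois)


def sphere_mask(
    center_mm: Iterable[float], radius_mm: float, grid: VoxelGrid
) -> np.ndarray:
    """Boolean volume of the voxels within `radius_mm` of `center_mm`.

    The centre is snapped to the nearest voxel centre first, so counts are
    deterministic functions of the grid; the boundary is inclusive.
    Raises if the snapped centre lies outside the grid (empty result).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be nonnegative")
    center_idx = grid.mm_to_index(np.asarray(tuple(center_mm), dtype=float))
    if not grid.contains_index(center_idx):
        raise ValueError(
            f"sphere centre {tuple(center_mm)} mm maps outside the grid"
        )
    center = grid.index_to_mm(center_idx)
    xx, yy, zz = grid.coordinate_volumes()
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return d2 <= radius_mm**2 + 1e-9


def ptsd_roi_set(
    grid: VoxelGrid,
    gm_mask: np.ndarray,
    specs: tuple[ROISpec, ...] = PTSD_ROI_SPECS,
) -> MaskSet:
    """The 8 PTSD-neurocircuitry spheres, each intersected with the GM mask.

    Spheres whose GM intersection is empty are retained (all-False volume)
    and listed in ``MaskSet.flagged``.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    out = MaskSet(name="ptsd_rois", grid=grid, provenance="fixed MNI coordinates")
    for spec in specs:
        try:
            sphere = sphere_mask(spec.center_mm, spec.radius_mm, grid)
        except ValueError:  # centre off-grid: retained as empty, flagged
            sphere = np.zeros(grid.dims, dtype=bool)
        roi = sphere & gm_mask
        out.rois[spec.name] = roi
        if not roi.any():
            out.flagged.append(spec.name)
    return out


def random_roi_sets(
    grid: VoxelGrid,
    gm_mask: np.ndarray,
    n_sets: int = 10,
    n_rois: int = 8,
    radius_mm: float = 6.0,
    seed: int = 0,
) -> list[MaskSet]:
    """`n_sets` sets of `n_rois` spheres centred on random GM voxels.

    Centres are drawn uniformly from GM voxels; spheres are intersected with
    GM (so boundary spheres are clipped) and may overlap, as nothing forbids
    it; the union de-duplicates overlapping voxels.  Deterministic per seed.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    gm_idx = np.argwhere(gm_mask)
    if gm_idx.shape[0] < n_rois:
        raise ValueError("gm_mask too small to host the requested ROI centres")
    rng = np.random.default_rng(seed)
    sets: list[MaskSet] = []
    for s in range(n_sets):
        ms = MaskSet(
            name=f"random_rois_{s + 1:02d}",
            grid=grid,
            provenance=f"random GM centres, seed={seed}, set={s + 1}",
        )
        picks = gm_idx[rng.choice(gm_idx.shape[0], size=n_rois, replace=False)]
        for r, idx in enumerate(picks):
            center = grid.index_to_mm(idx)
            roi = sphere_mask(center, radius_mm, grid) & gm_mask
            ms.rois[f"roi_{r + 1:02d}"] = roi
        sets.append(ms)
    return sets


def mask_complement(gm_mask: np.ndarray, roi_set: MaskSet) -> np.ndarray:
    """GM voxels outside the ROI set: complement partitions GM with the union."""
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if roi_set.grid.dims != gm_mask.shape:
        raise ValueError("gm_mask and roi_set must live on the same grid")
    return gm_mask & ~roi_set.union()


def group_gm_mask(gm_masks: Iterable[np.ndarray]) -> np.ndarray:
    """Group GM mask: voxels present in at least half of the subjects."""
    masks = [np.asarray(m, dtype=bool) for m in gm_masks]
    if not masks:
        raise ValueError("need at least one subject mask")
    counts = np.sum(masks, axis=0)
    return counts >= (len(masks) / 2.0)
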