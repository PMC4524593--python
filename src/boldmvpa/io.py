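"""On-disk formats: NIfTI-1 runs and masks, motion text, covariate/manifest TSV.

A subject directory contains one 4-D NIfTI per run, one whitespace-delimited
6-column motion file per run (one row per TR), NIfTI label volumes for the
tissue masks, a ``covariates.tsv`` and a ``manifest.tsv`` listing the run
files with condition and repetition.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, MotionParams, SubjectDataset, VoxelGrid

__all__ = [
    "save_run",
    "load_run",
    "save_subject",
    "load_subject",
    "save_mask",
    "load_mask",
    "write_manifest",
]


def _nifti(data: np.ndarray, grid: VoxelGrid) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=grid.affine)


def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    voxel = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], voxel):
        raise ValueError("only diagonal isotropic affines are supported")
    return VoxelGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        voxel_size_mm=voxel,
        origin_mm=tuple(float(x) for x in aff[:3, 3]),
    )


def save_run(run: BoldRun, bold_path: Path, motion_path: Path) -> None:
    nib.save(_nifti(run.data, run.grid), str(bold_path))
    np.savetxt(motion_path, run.motion.values, fmt="%.8f")


def load_run(
    bold_path: Path,
    motion_path: Path,
    tr_seconds: float,
    condition: str,
    repetition: int,
) -> BoldRun:
    img = nib.load(str(bold_path))
    grid = _grid_from_img(img)
    motion = MotionParams(np.loadtxt(motion_path, ndmin=2))
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=float),
        grid=grid,
        tr_seconds=tr_seconds,
        condition=condition,
        repetition=repetition,
        motion=motion,
    )


def save_mask(mask: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=grid.affine),
        str(path),
    )


def load_mask(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, _grid_from_img(img)


def save_subject(subject: SubjectDataset, out_dir: Path) -> Path:
    """Write a subject directory (runs, motion, masks, covariates, manifest)."""
    out_dir = Path(out_dir) / subject.subject_id
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for run in subject.runs:
        stem = f"{subject.subject_id}_cond-{run.condition}_rep-{run.repetition}"
        bold = out_dir / f"{stem}_bold.nii.gz"
        motion = out_dir / f"{stem}_motion.txt"
        save_run(run, bold, motion)
        records.append(
            {
                "bold_file": bold.name,
                "motion_file": motion.name,
                "condition": run.condition,
                "repetition": run.repetition,
                "tr_seconds": run.tr_seconds,
            }
        )
    pd.DataFrame(records).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    for name in ("gm", "wm", "csf"):
        save_mask(getattr(subject, f"{name}_mask"), subject.grid,
                  out_dir / f"{name}_mask.nii.gz")
    cov = dict(subject.covariates)
    cov["subject"] = subject.subject_id
    pd.DataFrame([cov]).to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    return out_dir


def load_subject(subject_dir: Path) -> SubjectDataset:
    subject_dir = Path(subject_dir)
    manifest = pd.read_csv(subject_dir / "manifest.tsv", sep="\t")
    runs = [
        load_run(
            subject_dir / row.bold_file,
            subject_dir / row.motion_file,
            tr_seconds=float(row.tr_seconds),
            condition=str(row.condition),
            repetition=int(row.repetition),
        )
        for row in manifest.itertuples()
    ]
    gm, _ = load_mask(subject_dir / "gm_mask.nii.gz")
    wm, _ = load_mask(subject_dir / "wm_mask.nii.gz")
    csf, _ = load_mask(subject_dir / "csf_mask.nii.gz")
    cov = pd.read_csv(subject_dir / "covariates.tsv", sep="\t").iloc[0].to_dict()
    subject_id = str(cov.pop("subject", subject_dir.name))
    return SubjectDataset(
        runs=runs, gm_mask=gm, wm_mask=wm, csf_mask=csf,
        covariates=cov, subject_id=subject_id,
    )


def write_manifest(path: Path, payload: dict) -> None:
    """JSON manifest (config echo, seeds, package versions) for provenance."""
    import boldmvpa

    payload = dict(payload)
    payload.setdefault("boldmvpa_version", boldmvpa.__version__)
    payload.setdefault("numpy_version", np.__version__)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
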