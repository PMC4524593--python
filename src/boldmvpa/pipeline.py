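"""Orchestration of the full permutation experiment.

A subject's decoding is evaluated over the cross of three methodological
factors: spatial smoothing (on/off), number of run repetitions per condition
(1-5), and voxel-selection mask (whole GM, circuit ROI spheres, GM minus
those spheres, random ROI sets).  :func:`run_subject` computes every
configured cell and returns a long-format results table; cells are compared
across subjects with paired tests.

All randomness derives from one global seed through documented per-component
offsets, so any single cell is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import SubjectDataset
from .decode import (
    CVConfig,
    SVMConfig,
    build_features,
    random_roi_accuracy,
    run_cv,
)
from .masks import MaskSet, mask_complement, ptsd_roi_set, random_roi_sets
from .preprocess import SmoothingConfig, preprocess_run
from .simulate import SimConfig

__all__ = [
    "ExperimentConfig",
    "preprocess_subject",
    "resolve_masks",
    "run_subject",
    "compare_cells",
]

MASK_CHOICES = ("gm", "ptsd_rois", "gm_minus_rois", "random_rois")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one permutation experiment.

    ``smoothing`` is "on", "off" or "both"; ``k_runs_values`` a subset of
    1..5; ``masks`` a subset of :data:`MASK_CHOICES`.  `seed` is the global
    seed from which CV fold assignment and random-ROI placement derive.
    """

    smoothing: str = "both"
    k_runs_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    masks: tuple[str, ...] = MASK_CHOICES
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    smoothing_cfg: SmoothingConfig = field(default_factory=SmoothingConfig)
    sim: SimConfig | None = None
    n_random_sets: int = 10
    n_random_rois: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing not in ("on", "off", "both"):
            raise ValueError("smoothing must be 'on', 'off' or 'both'")
        if not self.k_runs_values:
            raise ValueError("k_runs_values must be nonempty")
        if not self.masks:
            raise ValueError("masks must be nonempty")
        unknown = set(self.masks) - set(MASK_CHOICES)
        if unknown:
            raise ValueError(f"unknown masks: {sorted(unknown)}")

    @property
    def smoothing_arms(self) -> tuple[bool, ...]:
        return {"on": (True,), "off": (False,), "both": (False, True)}[self.smoothing]

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("smoothing", "seed", "n_random_sets", "n_random_rois"):
            if key in raw:
                kwargs[key] = raw[key]
        if "k_runs_values" in raw:
            kwargs["k_runs_values"] = tuple(int(k) for k in raw["k_runs_values"])
        if "masks" in raw:
            kwargs["masks"] = tuple(raw["masks"])
        if "svm" in raw:
            kwargs["svm"] = SVMConfig(**raw["svm"])
        if "cv" in raw:
            kwargs["cv"] = CVConfig(**raw["cv"])
        if "smoothing_cfg" in raw:
            kwargs["smoothing_cfg"] = SmoothingConfig(**raw["smoothing_cfg"])
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**{
                k: tuple(v) if k == "grid_dims" else v for k, v in raw["sim"].items()
            })
        return cls(**kwargs)


def resolve_masks(
    subject: SubjectDataset, cfg: ExperimentConfig
) -> dict[str, object]:
    """Build the configured voxel selections on the subject's grid.

    ``ptsd_rois`` uses the fixed MNI coordinates when the grid covers them;
    on desk-scale phantom grids that do not reach those coordinates, a
    deterministic stand-in set of spheres placed within the phantom GM is
    used instead (provenance recorded on the MaskSet).  ``random_rois``
    resolves to a *list* of MaskSets (the median-over-sets rule applies).
    """
    out: dict[str, object] = {}
    gm = subject.gm_mask
    grid = subject.grid
    roi_set: MaskSet | None = None
    if {"ptsd_rois", "gm_minus_rois"} & set(cfg.masks):
        roi_set = ptsd_roi_set(grid, gm)
        if len(roi_set.flagged) == len(roi_set.rois):
            # phantom grid: none of the MNI spheres intersect this GM
            roi_set = random_roi_sets(
                grid, gm, n_sets=1, n_rois=cfg.n_random_rois, seed=cfg.seed + 7919
            )[0]
            roi_set.name = "ptsd_rois"
            roi_set.provenance = (
                "phantom stand-in circuit ROIs (grid does not cover MNI coordinates); "
                f"seed={cfg.seed + 7919}"
            )
    for name in cfg.masks:
        if name == "gm":
            out[name] = gm
        elif name == "ptsd_rois":
            out[name] = roi_set
        elif name == "gm_minus_rois":
            out[name] = mask_complement(gm, roi_set)
        elif name == "random_rois":
            out[name] = random_roi_sets(
                grid, gm, n_sets=cfg.n_random_sets,
                n_rois=cfg.n_random_rois, seed=cfg.seed + 104729,
            )
    return out


def preprocess_subject(
    subject: SubjectDataset,
    smoothed: bool = False,
    cfg: ExperimentConfig | None = None,
) -> SubjectDataset:
    """Run the default preprocessing pipeline over every run of a subject.

    Computes the per-voxel session baseline once and applies nuisance
    regression, optional blur-to-FWHM smoothing, detrending and
    session-anchored percent-signal-change scaling to each run.
    """
    return _preprocess_subject(subject, cfg or ExperimentConfig(), smoothed)


def _preprocess_subject(
    subject: SubjectDataset, cfg: ExperimentConfig, smoothed: bool
) -> SubjectDataset:
    smoothing = cfg.smoothing_cfg if smoothed else None
    # session-level per-voxel baseline: anchors PSC so that between-run
    # (condition) mean differences survive per-run preprocessing
    baseline = np.mean([r.data.mean(axis=3) for r in subject.runs], axis=0)
    return subject.map_runs(
        lambda r: preprocess_run(
            r, subject.gm_mask, subject.wm_mask, subject.csf_mask,
            smoothing=smoothing, session_baseline=baseline,
        )
    )


def run_subject(
    subject: SubjectDataset,
    cfg: ExperimentConfig,
    preprocessed: Mapping[bool, SubjectDataset] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compute every configured (smoothing x k_runs x mask) cell.

    Returns a long-format results table (one record per cell: accuracy,
    sensitivity, specificity, feature count, seed) and a dict of median
    weight maps keyed by cell.  Per-cell failures are recorded in the table
    (``error`` column) and do not abort the experiment.  Pass `preprocessed`
    to reuse already-preprocessed datasets across calls.
    """
    records = []
    weight_maps: dict[tuple, np.ndarray] = {}
    preprocessed = dict(preprocessed) if preprocessed else {}
    for smoothed in cfg.smoothing_arms:
        if smoothed not in preprocessed:
            preprocessed[smoothed] = _preprocess_subject(subject, cfg, smoothed)
        prep = preprocessed[smoothed]
        masks = resolve_masks(prep, cfg)
        for k in cfg.k_runs_values:
            for mask_name, mask in masks.items():
                cell_seed = int(
                    (cfg.seed * 1009 + k * 101 + (1 if smoothed else 0)) % (2**31)
                )
                cv = CVConfig(n_folds=cfg.cv.n_folds, seed=cell_seed)
                rec = {
                    "subject": subject.subject_id,
                    "smoothing": "on" if smoothed else "off",
                    "k_runs": k,
                    "mask": mask_name,
                    "seed": cell_seed,
                    "error": "",
                }
                try:
                    if mask_name == "random_rois":
                        med, results = random_roi_accuracy(
                            prep, mask, k, cfg.svm, cv
                        )
                        rec.update(
                            accuracy=med,
                            sensitivity=float(np.median([r.sensitivity for r in results])),
                            specificity=float(np.median([r.specificity for r in results])),
                            n_features=int(np.median([r.n_features for r in results])),
                        )
                    else:
                        vox = mask.union() if isinstance(mask, MaskSet) else mask
                        feats = build_features(prep, vox, k)
                        res = run_cv(feats, cfg.svm, cv)
                        rec.update(
                            accuracy=res.accuracy,
                            sensitivity=res.sensitivity,
                            specificity=res.specificity,
                            n_features=res.n_features,
                        )
                        weight_maps[(subject.subject_id, rec["smoothing"], k, mask_name)] = (
                            res.weight_map
                        )
                except Exception as err:  # per-cell failure: record, continue
                    rec.update(
                        accuracy=np.nan, sensitivity=np.nan,
                        specificity=np.nan, n_features=0, error=str(err),
                    )
                records.append(rec)
    return pd.DataFrame(records), weight_maps


def compare_cells(
    results: pd.DataFrame,
    cell_a: Mapping[str, object],
    cell_b: Mapping[str, object],
    test: str = "paired_t",
) -> tuple[float, float]:
    """Paired test across subjects on median CV accuracies of two cells.

    Each cell is selected by column filters (e.g.
    ``{"mask": "gm", "k_runs": 3, "smoothing": "on"}``); both must cover the
    same subjects.  Returns (statistic, p); identical cells give (0, 1).
    """

    def select(cell):
        df = results
        for col, val in cell.items():
            df = df[df[col] == val]
        return df.set_index("subject")["accuracy"]

    a = select(cell_a)
    b = select(cell_b)
    if set(a.index) != set(b.index):
        raise ValueError("cells cover different subject sets")
    b = b.loc[a.index]
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if test == "paired_t":
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)
    if test == "wilcoxon":
        _, p = stats.wilcoxon(a, b)
        return float(diff.mean()), float(p)
    raise ValueError(f"unknown test {test!r}")
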