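"""Framewise displacement and the motion-control classifier.

The control analysis asks whether condition decoding could be explained by
head-motion artifact: the same features, CV machinery and SVM settings as
the condition decoder are reused with the labels replaced by a high/low
median split of framewise displacement (FD).  On data whose noise is
independent of motion, this control classifier should sit at chance while
the condition classifier does not.

FD here is the sum of absolute temporal differences of the six motion
parameters in their native units (mm and degrees); no lever-arm conversion
of the rotations is applied.
"""

from __future__ import annotations

import numpy as np

from .core import MotionParams, SubjectDataset
from .decode import CVConfig, CVResult, SVMConfig, build_features, run_cv

__all__ = [
    "DegenerateSplitError",
    "framewise_displacement",
    "median_split_labels",
    "motion_control_cv",
    "HIGH",
    "LOW",
]

HIGH = "high_motion"
LOW = "low_motion"


class DegenerateSplitError(ValueError):
    """All FD values identical: no median split exists."""


def framewise_displacement(motion: MotionParams) -> np.ndarray:
    """Per-TR FD: sum over the 6 parameters of |R_t - R_{t-1}|; FD_0 = 0."""
    R = motion.values
    if R.shape[0] < 2:
        raise ValueError("framewise displacement requires at least 2 TRs")
    fd = np.zeros(R.shape[0])
    fd[1:] = np.abs(np.diff(R, axis=0)).sum(axis=1)
    return fd


def median_split_labels(fd: np.ndarray) -> np.ndarray:
    """High/low labels from the FD median; exact-median ties labelled low."""
    fd = np.asarray(fd, dtype=float)
    if fd.size < 2:
        raise ValueError("median split requires at least 2 TRs")
    if np.allclose(fd, fd[0]):
        raise DegenerateSplitError("all FD values are identical")
    med = np.median(fd)
    return np.where(fd > med, HIGH, LOW)


def motion_control_cv(
    subject: SubjectDataset,
    gm_mask: np.ndarray,
    k_runs: int = 3,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
) -> CVResult:
    """The motion-control classifier: condition features, motion labels.

    Features are built exactly as for condition decoding (the same
    :func:`~boldmvpa.decode.build_features` call, all GM voxels, first
    `k_runs` runs per condition); FD is concatenated across those same runs
    in the same row order, median-split once over the concatenation, and the
    resulting high/low labels replace the condition labels.  Everything else
    (z-scoring, folds, SVM) is shared with the condition decoder by
    construction.
    """
    features = build_features(subject, gm_mask, k_runs)
    # recover the included runs in feature-row order and concatenate their FD
    order = {id(r): i for i, r in enumerate(subject.runs)}
    selected = []
    for condition in subject.conditions:
        selected.extend(subject.runs_for(condition, k_runs))
    selected.sort(key=lambda r: order[id(r)])
    fd = np.concatenate([framewise_displacement(r.motion) for r in selected])
    if fd.size != features.n_rows:
        raise RuntimeError("FD length does not match feature rows")  # pragma: no cover
    labels = median_split_labels(fd)
    return run_cv(features.with_labels(labels), svm, cv, positive_label=HIGH)
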