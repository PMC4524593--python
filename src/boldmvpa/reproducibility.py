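"""Reproducibility of feature-weight maps across models trained with 1-5 runs.

For each subject, decoders are trained with the first k repetitions per
condition (k = 1..5) and the resulting median weight maps are compared by
spatial Pearson correlation, Fisher r-to-z transformed to improve normality.
The per-model summary is the median of that model's similarities with all
other models; across subjects, models are compared with a paired
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import SubjectDataset
from .decode import CVConfig, SVMConfig, build_features, run_cv

__all__ = [
    "Z_CAP",
    "SimilarityMatrix",
    "fisher_z",
    "map_similarity",
    "cross_model_similarity",
    "median_cross_model_similarity",
    "compare_model_similarity_across_subjects",
]

#: Sentinel magnitude for |r| = 1 (arctanh(1 - 1e-16) order), keeping tables numeric.
Z_CAP = 18.7


def fisher_z(r: float) -> float:
    """Fisher r-to-z: arctanh(r).  Raises outside (-1, 1)."""
    r = float(r)
    if not -1.0 < r < 1.0:
        raise ValueError(f"fisher_z domain is (-1, 1), got r={r}")
    return float(np.arctanh(r))


def map_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Fisher-z of the Pearson correlation of two weight vectors.

    Perfect (anti)correlation is reported as the +-``Z_CAP`` sentinel rather
    than infinity.  Zero-variance input raises (degenerate map).
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("maps must have equal length >= 3")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance weight map")
    r = float(np.corrcoef(a, b)[0, 1])
    if r >= 1.0:
        return Z_CAP
    if r <= -1.0:
        return -Z_CAP
    return fisher_z(r)


@dataclass
class SimilarityMatrix:
    """Symmetric K x K table of Fisher-z map similarities, diagonal NaN."""

    values: np.ndarray
    k_values: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != len(self.k_values):
            raise ValueError("k_values length must match matrix size")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    def median_for(self, k: int) -> float:
        """Median of model k's similarities with all other models."""
        i = self.k_values.index(k)
        row = np.delete(self.values[i], i)
        return float(np.median(row))

    def to_frame(self):
        import pandas as pd

        labels = [f"k={k}" for k in self.k_values]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def cross_model_similarity(
    subject: SubjectDataset,
    mask: np.ndarray,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
) -> SimilarityMatrix:
    """Train a decoder per k and correlate the median weight maps pairwise.

    All models share the voxel selection `mask` (GM by default in callers),
    so the weight vectors are directly comparable.
    """
    svm = svm or SVMConfig()
    cv = cv or CVConfig()
    maps = []
    for k in k_values:
        feats = build_features(subject, mask, k)
        res = run_cv(feats, svm, CVConfig(n_folds=cv.n_folds, seed=cv.seed + k))
        maps.append(res.weight_map)
    K = len(k_values)
    M = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(i + 1, K):
            z = map_similarity(maps[i], maps[j])
            M[i, j] = M[j, i] = z
    return SimilarityMatrix(values=M, k_values=tuple(k_values))


def median_cross_model_similarity(matrix: SimilarityMatrix, k: int) -> float:
    """Median similarity of the k-run model with all other models."""
    return matrix.median_for(k)


def compare_model_similarity_across_subjects(
    cohort_matrices: Sequence[SimilarityMatrix],
    k_a: int,
    k_b: int,
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Paired comparison of per-subject median similarities, model a vs b.

    Returns (statistic, p).  The statistic is signed so that swapping
    ``k_a`` and ``k_b`` flips its sign: for the default signed-rank test it
    is the mean of the paired differences ``median(k_a) - median(k_b)``; for
    ``test="paired_t"`` it is the t statistic.
    Identical pairs give (0, 1).
    """
    if len(cohort_matrices) < 5:
        raise ValueError("need at least 5 subjects for a paired comparison")
    a = np.array([m.median_for(k_a) for m in cohort_matrices])
    b = np.array([m.median_for(k_b) for m in cohort_matrices])
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if test == "wilcoxon":
        _, p = stats.wilcoxon(a, b)
        return float(diff.mean()), float(p)
    if test == "paired_t":
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)
    raise ValueError(f"unknown test {test!r}")
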