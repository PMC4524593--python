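"""TR-level two-class decoding with an RBF-kernel SVM and k-fold CV.

Each TR (volume) of the included runs is one sample; features are the
z-scored percent-signal-change values of the voxels inside a mask.  A
radial-basis-function support vector machine (C = 100, the configuration of
classical BOLD-decoding work) is trained and evaluated with randomized
10-fold cross-validation; accuracy is the *median* fold accuracy, and the
reported feature-weight map is the voxel-wise median across folds of the
per-fold weight vectors.

A note on "feature weights" of a nonlinear SVM: the RBF classifier has no
primal weight vector in voxel space.  Following the convention of the
classical solver outputs, the weight of voxel j is the support-vector-
coefficient-weighted sum sum_i alpha_i y_i x_ij — the linear pre-image of the
dual solution.  It localizes the discriminative signal well in practice but
is not the decision function's gradient; interpret with care.

The statsmodels-style surface is :class:`SubjectDecoder` (model) whose
``fit()`` returns :class:`DecodingResults`; the underlying operations
(:func:`build_features`, :func:`cv_split`, :func:`run_cv`, ...) are public.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .core import TRAUMA, SubjectDataset, VoxelGrid

__all__ = [
    "FeatureMatrix",
    "SVMConfig",
    "CVConfig",
    "CVResult",
    "DegenerateFoldError",
    "build_features",
    "cv_split",
    "train_and_weights",
    "run_cv",
    "random_roi_accuracy",
    "SubjectDecoder",
    "DecodingResults",
]


class DegenerateFoldError(ValueError):
    """A CV fold whose training rows contain a single class."""

    def __init__(self, fold: int, message: str | None = None):
        self.fold = fold
        super().__init__(message or f"fold {fold}: training rows contain one class")


@dataclass
class FeatureMatrix:
    """TR-by-voxel feature matrix with labels and provenance.

    Rows are TRs of the included runs in temporal order; columns are the
    masked voxels (order fixed by ``voxel_index``, the flat index of each
    column's voxel on ``grid``); values are z-scored per voxel over the
    included rows.
    """

    X: np.ndarray
    labels: np.ndarray
    run_index: np.ndarray
    repetition: np.ndarray
    voxel_index: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain NaN/Inf")
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.run_index) == len(self.repetition) == n):
            raise ValueError("row metadata length mismatch")
        if len(self.voxel_index) != self.X.shape[1]:
            raise ValueError("voxel_index length must equal column count")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_labels(self, labels: np.ndarray) -> "FeatureMatrix":
        """Same features, different labels (the motion-control construction)."""
        return FeatureMatrix(
            X=self.X,
            labels=np.asarray(labels),
            run_index=self.run_index,
            repetition=self.repetition,
            voxel_index=self.voxel_index,
            grid=self.grid,
        )


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM settings: C = 100; gamma defaults to 1 / n_features."""

    C: float = 100.0
    gamma: float | str = "n_features"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")

    def resolve_gamma(self, n_features: int) -> float | str:
        if self.gamma == "n_features":
            return 1.0 / n_features
        return self.gamma


@dataclass(frozen=True)
class CVConfig:
    """Randomized k-fold assignment of TRs (default 10 folds)."""

    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class CVResult:
    """Cross-validation outcome: rates, per-fold detail, median weight map."""

    fold_accuracies: np.ndarray
    accuracy: float  # median across folds
    sensitivity: float  # pooled over folds, positive class
    specificity: float
    weight_map: np.ndarray  # per-voxel median across folds
    fold_weights: np.ndarray  # (n_folds, P)
    positive_label: str
    n_features: int

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")


def build_features(
    subject: SubjectDataset,
    mask: np.ndarray,
    k_runs: int,
    zscore: str = "all",
) -> FeatureMatrix:
    """Stack the first `k_runs` repetitions of each condition into a TR x voxel
    matrix restricted to `mask`, z-scored per voxel.

    ``zscore="all"`` normalizes with statistics of the full included
    timeseries (matching the classical description; slightly leaky across CV
    folds).  ``zscore="none"`` skips normalization — the leakage-safe
    alternative is to z-score per training fold downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    voxel_index = np.flatnonzero(mask.ravel())
    blocks, labels, run_idx, reps = [], [], [], []
    selected: list = []
    for condition in subject.conditions:
        selected.extend(subject.runs_for(condition, k_runs))
    # preserve the subject's run ordering (acquisition order)
    order = {id(r): i for i, r in enumerate(subject.runs)}
    selected.sort(key=lambda r: order[id(r)])
    for i, run in enumerate(selected):
        flat = run.data.reshape(-1, run.n_trs)
        blocks.append(flat[voxel_index].T)
        labels.extend([run.condition] * run.n_trs)
        run_idx.extend([i] * run.n_trs)
        reps.extend([run.repetition] * run.n_trs)
    X = np.vstack(blocks)
    if zscore == "all":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    elif zscore != "none":
        raise ValueError(f"unknown zscore mode {zscore!r}")
    return FeatureMatrix(
        X=X,
        labels=np.asarray(labels),
        run_index=np.asarray(run_idx),
        repetition=np.asarray(reps),
        voxel_index=voxel_index,
        grid=subject.grid,
    )


def cv_split(n_rows: int, cfg: CVConfig) -> np.ndarray:
    """Random partition of rows into folds; sizes differ by at most one.

    Returns an integer fold id per row.  Deterministic per ``cfg.seed``.
    """
    if n_rows < cfg.n_folds:
        raise ValueError("need at least as many rows as folds")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_rows)
    assignment = np.empty(n_rows, dtype=int)
    for fold, rows in enumerate(np.array_split(perm, cfg.n_folds)):
        assignment[rows] = fold
    return assignment


def train_and_weights(
    X_train: np.ndarray, y_train: np.ndarray, cfg: SVMConfig
) -> tuple[SVC, np.ndarray]:
    """Fit the RBF SVM and extract the per-voxel weight vector.

    The weight vector is ``dual_coef_ @ support_vectors_`` — the linear
    pre-image of the dual solution.  Its sign convention follows the
    decision function (positive favours ``clf.classes_[1]``).  Raises
    ``ValueError`` on a single-class training set.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(
        C=cfg.C,
        kernel=cfg.kernel,
        gamma=cfg.resolve_gamma(X_train.shape[1]),
    )
    clf.fit(X_train, y_train)
    weights = (clf.dual_coef_ @ clf.support_vectors_).ravel()
    return clf, weights


def _infer_positive_label(classes: Sequence[str]) -> str:
    classes = list(classes)
    if TRAUMA in classes:
        return TRAUMA
    return sorted(classes)[-1]


def run_cv(
    features: FeatureMatrix,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
    positive_label: str | None = None,
) -> CVResult:
    """Full cross-validation of one feature matrix.

    Per fold: train on the other folds, test on the held-out fold.
    Accuracy is the median fold accuracy; sensitivity/specificity are pooled
    over the held-out predictions of all folds (well defined even when a
    small fold contains few positives); the weight map is the voxel-wise
    median of the per-fold weight vectors.
    """
    svm = svm or SVMConfig()
    cv = cv or CVConfig()
    classes = features.classes
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    pos = positive_label or _infer_positive_label(classes)
    assignment = cv_split(features.n_rows, cv)
    fold_acc = np.empty(cv.n_folds)
    fold_weights = np.empty((cv.n_folds, features.n_features))
    pooled_true, pooled_pred = [], []
    for fold in range(cv.n_folds):
        test = assignment == fold
        train = ~test
        y_train = features.labels[train]
        if len(np.unique(y_train)) < 2:
            raise DegenerateFoldError(fold)
        try:
            clf, w = train_and_weights(features.X[train], y_train, svm)
        except ValueError as err:  # pragma: no cover - defensive
            raise DegenerateFoldError(fold, str(err)) from err
        pred = clf.predict(features.X[test])
        fold_acc[fold] = np.mean(pred == features.labels[test])
        fold_weights[fold] = w if clf.classes_[1] == pos else -w
        pooled_true.append(features.labels[test])
        pooled_pred.append(pred)
    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    is_pos = y_true == pos
    sensitivity = float(np.mean(y_pred[is_pos] == pos)) if is_pos.any() else float("nan")
    specificity = (
        float(np.mean(y_pred[~is_pos] != pos)) if (~is_pos).any() else float("nan")
    )
    return CVResult(
        fold_accuracies=fold_acc,
        accuracy=float(np.median(fold_acc)),
        sensitivity=sensitivity,
        specificity=specificity,
        weight_map=np.median(fold_weights, axis=0),
        fold_weights=fold_weights,
        positive_label=pos,
        n_features=features.n_features,
    )


def random_roi_accuracy(
    subject: SubjectDataset,
    random_sets,
    k_runs: int,
    svm: SVMConfig | None = None,
    cv: CVConfig | None = None,
) -> tuple[float, list[CVResult]]:
    """Decode within each random ROI set; return the median of the per-set
    median accuracies and the per-set results."""
    if not random_sets:
        raise ValueError("need at least one ROI set")
    results = []
    for ms in random_sets:
        feats = build_features(subject, ms.union(), k_runs)
        results.append(run_cv(feats, svm, cv))
    return float(np.median([r.accuracy for r in results])), results


class SubjectDecoder:
    """Within-subject brain-state decoder (model object).

    Parameters
    ----------
    subject : SubjectDataset
        Preprocessed runs (the decoder does not preprocess).
    mask : ndarray of bool
        Voxel selection for the features (e.g. the GM mask).
    k_runs : int
        Repetitions per condition to include (the first k, default 3 —
        the efficiency/accuracy sweet spot of the design).
    svm, cv : SVMConfig, CVConfig
    zscore : {"all", "none"}
        Feature normalization mode, see :func:`build_features`.
    """

    def __init__(
        self,
        subject: SubjectDataset,
        mask: np.ndarray,
        k_runs: int = 3,
        svm: SVMConfig | None = None,
        cv: CVConfig | None = None,
        zscore: str = "all",
    ):
        self.subject = subject
        self.mask = np.asarray(mask, dtype=bool)
        self.k_runs = k_runs
        self.svm = svm or SVMConfig()
        self.cv = cv or CVConfig()
        self.zscore = zscore

    @classmethod
    def from_dataset(cls, subject: SubjectDataset, **kwargs) -> "SubjectDecoder":
        """Decoder over the subject's own GM mask (the default analysis)."""
        kwargs.setdefault("mask", subject.gm_mask)
        return cls(subject, **kwargs)

    def fit(self) -> "DecodingResults":
        features = build_features(self.subject, self.mask, self.k_runs, self.zscore)
        cvres = run_cv(features, self.svm, self.cv)
        return DecodingResults(model=self, features=features, cvres=cvres)


@dataclass
class DecodingResults:
    """Fitted decoding results: rates, weight map, and reporting helpers."""

    model: SubjectDecoder
    features: FeatureMatrix
    cvres: CVResult

    @property
    def accuracy(self) -> float:
        return self.cvres.accuracy

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.cvres.fold_accuracies

    @property
    def sensitivity(self) -> float:
        return self.cvres.sensitivity

    @property
    def specificity(self) -> float:
        return self.cvres.specificity

    @property
    def weight_map(self) -> np.ndarray:
        return self.cvres.weight_map

    def weight_volume(self) -> np.ndarray:
        """Reshape the weight vector back into 3-D brain shape."""
        vol = np.zeros(self.features.grid.dims)
        vol.ravel()[self.features.voxel_index] = self.cvres.weight_map
        return vol

    def summary(self) -> str:
        c = self.cvres
        lines = [
            "Subject decoding results",
            "=" * 44,
            f"subject:            {self.model.subject.subject_id}",
            f"runs per condition: {self.model.k_runs}",
            f"rows (TRs):         {self.features.n_rows}",
            f"features (voxels):  {self.features.n_features}",
            f"folds:              {len(c.fold_accuracies)}",
            f"median accuracy:    {c.accuracy:.3f}",
            f"sensitivity ({c.positive_label}): {c.sensitivity:.3f}",
            f"specificity:        {c.specificity:.3f}",
            f"fold accuracy range: {c.fold_accuracies.min():.3f}"
            f" - {c.fold_accuracies.max():.3f}",
        ]
        return "\n".join(lines)

    def plot_weights(self, axis: int = 2, ax=None):
        """Mid-volume slice of the weight map (diagnostic plot)."""
        import matplotlib.pyplot as plt

        vol = self.weight_volume()
        sl = [slice(None)] * 3
        sl[axis] = vol.shape[axis] // 2
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(vol[tuple(sl)].T, origin="lower", cmap="RdBu_r")
        ax.figure.colorbar(im, ax=ax, label="SVM feature weight")
        ax.set_title(f"median weight map, slice axis {axis}")
        return ax
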