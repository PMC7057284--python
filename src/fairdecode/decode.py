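"""ROI decoding of game type from trial patterns.

The classification pipeline mirrors standard MVPA practice: per-voxel
standardization, univariate ANOVA feature selection keeping the 1000
highest-F voxels, and a linear support vector machine at C = 1, all three
steps nested inside 6-fold cross-validation so that no statistic of the
held-out trials can leak into the classifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .glm import TrialPatterns
from .volumes import ClusterSet, MaskVolume

__all__ = [
    "DecodeConfig",
    "DecodingResult",
    "make_folds",
    "anova_feature_scores",
    "RoiDecoder",
    "crossval_decode",
    "roi_decode_battery",
]


@dataclass
class DecodeConfig:
    """Decoding hyper-parameters.

    ``n_features`` is the top-k of the ANOVA selection; ``None`` disables
    selection (the individual-ROI and searchlight regimes).  ``scaling``
    selects per-voxel z-scoring fit on the training fold
    (``per_voxel_trainfit``, default) or per-pattern z-scoring across voxels
    (``per_pattern``, needs no fitting).  ``fold_scheme`` assigns stratified
    folds in chronological blocks by default; ``random`` shuffles within
    class under ``seed``.
    """

    n_folds: int = 6
    svm_cost: float = 1.0
    n_features: int | None = 1000
    scaling: str = "per_voxel_trainfit"
    fold_scheme: str = "chronological"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.scaling not in ("per_voxel_trainfit", "per_pattern"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        if self.fold_scheme not in ("chronological", "random"):
            raise ValueError(f"unknown fold scheme {self.fold_scheme!r}")


@dataclass
class DecodingResult:
    """Cross-validated accuracy for one subject x ROI x condition filter."""

    subject_id: str
    roi_name: str
    accuracy: float
    per_fold_accuracies: np.ndarray
    fold_sizes: np.ndarray
    n_trials: int
    condition_pair: tuple[str, str]
    condition: str = "social"
    n_selected_per_fold: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self) -> None:
        self.per_fold_accuracies = np.asarray(self.per_fold_accuracies, float)
        self.fold_sizes = np.asarray(self.fold_sizes, int)
        weighted = float(np.average(self.per_fold_accuracies,
                                    weights=self.fold_sizes))
        if not np.isclose(self.accuracy, weighted):
            raise ValueError("accuracy must be the fold-size weighted mean")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def make_folds(
    labels: np.ndarray,
    n_folds: int,
    seed: int = 0,
    scheme: str = "chronological",
) -> np.ndarray:
    """Stratified fold assignment, one integer fold id per trial.

    Within each class the trials (taken in the given, i.e. chronological,
    order) are split into ``n_folds`` contiguous blocks; with 12 trials per
    class and 6 folds every fold holds exactly 2 trials of each class.  The
    ``random`` scheme shuffles the within-class order first, deterministically
    under ``seed``.
    """
    labels = np.asarray(labels)
    if scheme not in ("chronological", "random"):
        raise ValueError(f"unknown fold scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} trials, fewer than {n_folds} folds")
        if scheme == "random":
            idx = rng.permutation(idx)
        # block j of the class order goes to fold j (balanced within +-1)
        folds[idx] = (np.arange(len(idx)) * n_folds) // len(idx)
    return folds


def anova_feature_scores(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (voxel), computed on ``x`` only.

    Features with zero within-class variance but distinct class means are
    perfectly separating; their F is set to +inf so they rank first.  Fully
    constant features get F = 0.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = x.shape[0]
    k = len(classes)
    grand = x.mean(axis=0)
    ss_between = np.zeros(x.shape[1])
    ss_within = np.zeros(x.shape[1])
    for cls in classes:
        grp = x[labels == cls]
        if len(grp) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 trials")
        mu = grp.mean(axis=0)
        ss_between += len(grp) * (mu - grand) ** 2
        ss_within += ((grp - mu) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f[(ms_within == 0) & (ms_between > 0)] = np.inf
    f[(ms_within == 0) & (ms_between == 0)] = 0.0
    return f


class RoiDecoder(BaseEstimator, ClassifierMixin):
    """Scale -> select -> linear SVM, as one scikit-learn classifier.

    All three steps are fit on the training data passed to :meth:`fit`;
    :meth:`predict` applies the frozen transforms to new patterns.  Used per
    cross-validation fold so that scaling and voxel selection never see the
    held-out trials.
    """

    def __init__(self, n_features: int | None = 1000, svm_cost: float = 1.0,
                 scaling: str = "per_voxel_trainfit"):
        self.n_features = n_features
        self.svm_cost = svm_cost
        self.scaling = scaling

    def _scale_fit(self, x: np.ndarray) -> None:
        if self.scaling == "per_voxel_trainfit":
            self.mean_ = x.mean(axis=0)
            sd = x.std(axis=0)
            self.scale_ = np.where(sd == 0, 1.0, sd)
        elif self.scaling != "per_pattern":
            raise ValueError(f"unknown scaling mode {self.scaling!r}")

    def _scale_apply(self, x: np.ndarray) -> np.ndarray:
        if self.scaling == "per_pattern":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            return (x - mu) / np.where(sd == 0, 1.0, sd)
        return (x - self.mean_) / self.scale_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RoiDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_trials, n_voxels) matching y")
        self.classes_ = np.unique(y)
        self._scale_fit(X)
        xs = self._scale_apply(X)
        if self.n_features is not None and self.n_features < xs.shape[1]:
            scores = anova_feature_scores(xs, y)
            # stable top-k: rank by (-F, index) so ties keep voxel order
            order = np.lexsort((np.arange(len(scores)), -scores))
            self.selected_ = np.sort(order[: self.n_features])
        else:
            self.selected_ = np.arange(xs.shape[1])
        self.svm_ = SVC(kernel="linear", C=self.svm_cost)
        self.svm_.fit(xs[:, self.selected_], y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        xs = self._scale_apply(np.asarray(X, dtype=float))
        return self.svm_.predict(xs[:, self.selected_])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        xs = self._scale_apply(np.asarray(X, dtype=float))
        return self.svm_.decision_function(xs[:, self.selected_])


def cross_val_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    config: DecodeConfig,
    selection_scope: str = "fold",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold accuracies for patterns ``x`` and labels ``y``.

    ``selection_scope='fold'`` nests scaling and feature selection inside
    each training fold (the correct procedure).  ``'all'`` deliberately fits
    the voxel selection on the full data before cross-validation -- a broken
    mode retained to demonstrate the optimistic bias it produces on null data.

    Returns (per_fold_accuracy, fold_sizes, n_selected_per_fold).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if selection_scope not in ("fold", "all"):
        raise ValueError(f"unknown selection scope {selection_scope!r}")
    folds = make_folds(y, config.n_folds, seed=config.seed,
                       scheme=config.fold_scheme)
    if selection_scope == "all" and config.n_features is not None \
            and config.n_features < x.shape[1]:
        scores = anova_feature_scores(x, y)
        order = np.lexsort((np.arange(len(scores)), -scores))
        x = x[:, np.sort(order[: config.n_features])]
    accs, sizes, selected = [], [], []
    for f in range(config.n_folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: training set contains a single class")
        dec = RoiDecoder(n_features=config.n_features if selection_scope == "fold" else None,
                         svm_cost=config.svm_cost, scaling=config.scaling)
        dec.fit(x[train], y[train])
        pred = dec.predict(x[test])
        accs.append(float(np.mean(pred == y[test])))
        sizes.append(int(test.sum()))
        selected.append(len(dec.selected_))
    return np.asarray(accs), np.asarray(sizes, int), np.asarray(selected, int)


def crossval_decode(
    patterns: TrialPatterns,
    condition_pair: tuple[str, str] = ("UG", "DG"),
    roi_voxels: np.ndarray | None = None,
    config: DecodeConfig | None = None,
    roi_name: str = "roi",
    condition: str = "social",
    selection_scope: str = "fold",
) -> DecodingResult:
    """Cross-validated decoding of game type within one set of voxels.

    ``roi_voxels`` indexes pattern columns (``None`` = all voxels).  Trials
    whose ``game`` label is not in ``condition_pair`` are dropped.  Feature
    selection keeps ``config.n_features`` voxels per training fold; ROIs with
    fewer voxels use them all.
    """
    config = config or DecodeConfig()
    keep = patterns.labels["game"].isin(condition_pair).to_numpy()
    y = patterns.labels.loc[keep, "game"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError(f"both conditions of {condition_pair} must be present")
    x = patterns.values[keep]
    if roi_voxels is not None:
        roi_voxels = np.asarray(roi_voxels, dtype=int)
        if roi_voxels.size == 0:
            raise ValueError("ROI contains no voxels")
        if roi_voxels.max() >= x.shape[1]:
            raise ValueError("ROI voxel index outside the pattern grid")
        x = x[:, roi_voxels]
    accs, sizes, selected = cross_val_accuracy(x, y, config, selection_scope)
    return DecodingResult(
        subject_id=patterns.subject_id, roi_name=roi_name,
        accuracy=float(np.average(accs, weights=sizes)),
        per_fold_accuracies=accs, fold_sizes=sizes, n_trials=int(len(y)),
        condition_pair=tuple(condition_pair), condition=condition,
        n_selected_per_fold=selected)


def _mask_columns(patterns: TrialPatterns, mask_data: np.ndarray) -> np.ndarray:
    """Pattern-column indices covered by a 3-D mask; errors if the mask
    reaches voxels the patterns do not cover."""
    if mask_data.shape != patterns.grid_shape:
        raise ValueError("ROI grid does not match the pattern grid")
    lut = patterns.column_lookup()
    cols = lut[mask_data.astype(bool)]
    if np.any(cols < 0):
        raise ValueError("ROI extends outside the voxels covered by the patterns")
    return np.sort(cols)


def roi_decode_battery(
    patterns: TrialPatterns,
    rois: list[MaskVolume] | ClusterSet,
    config: DecodeConfig | None = None,
    opponent_filter: str = "human",
    condition_pair: tuple[str, str] = ("UG", "DG"),
) -> list[DecodingResult]:
    """Decode game type in each ROI after filtering trials by opponent.

    Whole-network masks (a list of :class:`MaskVolume`) go through the
    top-k ANOVA selection; individual clusters (a :class:`ClusterSet`) use
    every cluster voxel -- there the ROI itself is the feature selection.
    """
    config = config or DecodeConfig()
    if opponent_filter not in ("human", "computer"):
        raise ValueError(f"unknown opponent filter {opponent_filter!r}")
    condition = "social" if opponent_filter == "human" else "non_social"
    keep = (patterns.labels["opponent"] == opponent_filter).to_numpy()
    if not keep.any():
        raise ValueError(f"no trials with opponent {opponent_filter!r}")
    sub = patterns.select_trials(np.flatnonzero(keep))

    results: list[DecodingResult] = []
    if isinstance(rois, ClusterSet):
        from dataclasses import replace

        cluster_config = replace(config, n_features=None)
        for label in range(1, len(rois) + 1):
            cols = _mask_columns(sub, rois.label_volume == label)
            results.append(crossval_decode(
                sub, condition_pair, cols, cluster_config,
                roi_name=f"{rois.name}_{label:02d}", condition=condition))
    else:
        for roi in rois:
            cols = _mask_columns(sub, roi.data)
            results.append(crossval_decode(
                sub, condition_pair, cols, config,
                roi_name=roi.name, condition=condition))
    return results
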