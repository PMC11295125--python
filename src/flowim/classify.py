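"""Classifier training and evaluation harness.

Covers the shared machinery for both classifier families: stratified
85:15 train/test splitting, 8-fold dihedral augmentation of image
crops, a randomized hyperparameter search around a known-good random
forest configuration with MDI feature importances, accuracy-vs-
variability model selection, and quantification/correction of
class-proportion bias in mixed samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV

from .detect import ROI

TEST_FRACTION = 0.15

#: Reference hyperparameters: a configuration known to perform well on
#: morphology-feature tables; the randomized search brackets these.
RF_REFERENCE_PARAMS = {
    "n_estimators": 250,
    "min_samples_split": 5,
    "min_samples_leaf": 2,
    "max_features": "sqrt",
    "max_depth": 30,
    "bootstrap": False,
}

RF_SEARCH_SPACE = {
    "n_estimators": [100, 250, 400],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["sqrt", "log2"],
    "max_depth": [10, 30, None],
    "bootstrap": [True, False],
}


@dataclass
class LabeledLibrary:
    """Annotated training library: items with class labels and a split.

    ``items`` may hold ROIs (for image classifiers) or feature mappings
    (for feature-based classifiers).  ``split`` assigns each item to
    ``"train"`` or ``"test"`` once :func:`train_test_split` has run.
    """

    items: list
    labels: list
    classes: tuple
    split: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.items) != len(self.labels):
            raise ValueError("items and labels must align")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {unknown}")

    def __len__(self) -> int:
        return len(self.items)

    def subset(self, which: str) -> "LabeledLibrary":
        if self.split is None:
            raise ValueError("library has no split assignment yet")
        keep = [i for i, s in enumerate(self.split) if s == which]
        return LabeledLibrary(
            items=[self.items[i] for i in keep],
            labels=[self.labels[i] for i in keep],
            classes=self.classes,
            split=np.array([which] * len(keep)),
            seed=self.seed,
        )

    def content_hash(self) -> str:
        """Deterministic digest of crops/features and labels."""
        h = hashlib.sha256()
        for item, label in zip(self.items, self.labels):
            h.update(str(label).encode())
            if isinstance(item, ROI):
                h.update(np.ascontiguousarray(item.crop).tobytes())
            elif isinstance(item, dict):
                for k in sorted(item):
                    h.update(f"{k}={item[k]:.12g}".encode())
            else:
                h.update(np.ascontiguousarray(np.asarray(item)).tobytes())
        return h.hexdigest()


def train_test_split(
    lib: LabeledLibrary, test_fraction: float = TEST_FRACTION, seed: int = 0
) -> LabeledLibrary:
    """Stratified split: per class, round(test_fraction * n) test items."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(lib.labels, dtype=object)
    split = np.array(["train"] * len(lib), dtype=object)
    for cls in lib.classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 items")
        n_test = int(round(test_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_test, replace=False)
        split[chosen] = "test"
    return replace(lib, split=split, seed=seed)


def _dihedral_variants(img: np.ndarray) -> list[np.ndarray]:
    out = []
    for mirrored in (img, np.fliplr(img)):
        for k in range(4):
            out.append(np.ascontiguousarray(np.rot90(mirrored, k)))
    return out


def augment_8fold(rois: Sequence[ROI | np.ndarray]) -> list:
    """All 8 dihedral variants (4 rotations x optional mirror) per crop.

    Non-square crops are zero-padded to squares first so that every
    rotation has a consistent shape.  The identity transform is
    included, so n inputs yield exactly 8n outputs.
    """
    out = []
    for item in rois:
        img = item.crop if isinstance(item, ROI) else np.asarray(item)
        h, w = img.shape[:2]
        if h != w:
            side = max(h, w)
            pad = [(0, side - h), (0, side - w)] + [(0, 0)] * (img.ndim - 2)
            img = np.pad(img, pad)
        out.extend(_dihedral_variants(img))
    return out


def train_random_forest(
    X: pd.DataFrame,
    y: Sequence,
    search_budget: int = 25,
    seed: int = 0,
    cv: int = 3,
):
    """Fit a random forest with a randomized hyperparameter search.

    ``search_budget`` parameter combinations are sampled from
    :data:`RF_SEARCH_SPACE` and scored by macro-F1 under ``cv``-fold
    cross-validation on the training data; a budget of 0 skips the
    search and fits :data:`RF_REFERENCE_PARAMS` directly.

    Returns
    -------
    (model, importances)
        The fitted forest and its mean-decrease-in-impurity feature
        importances (a Series summing to 1, sorted descending).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train a classifier")
    if X.isna().any().any():
        raise ValueError("feature table contains missing values")
    if search_budget > 0:
        search = RandomizedSearchCV(
            RandomForestClassifier(random_state=seed),
            RF_SEARCH_SPACE,
            n_iter=search_budget,
            scoring="f1_macro",
            cv=cv,
            random_state=seed,
            n_jobs=1,
        )
        search.fit(X, y)
        model = search.best_estimator_
    else:
        model = RandomForestClassifier(random_state=seed, **RF_REFERENCE_PARAMS)
        model.fit(X, y)
    importances = pd.Series(
        model.feature_importances_, index=X.columns
    ).sort_values(ascending=False)
    return model, importances


@dataclass
class ConfusionMatrix:
    """Truth-by-prediction counts with per-class and overall accuracy."""

    counts: pd.DataFrame  # rows = truth, columns = prediction

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes: Sequence) -> "ConfusionMatrix":
        classes = list(classes)
        table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(y_true, y_pred):
            table.loc[t, p] += 1
        return cls(counts=table)

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.counts.index, dtype=float)
        totals = self.counts.sum(axis=1)
        return diag / totals.replace(0, np.nan)

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.values.sum()
        return float(np.trace(self.counts.values) / total) if total else float("nan")


def evaluate(model, X, y_true, classes: Sequence) -> ConfusionMatrix:
    """Confusion matrix of a fitted model on held-out data."""
    return ConfusionMatrix.from_predictions(y_true, model.predict(X), classes)


def select_model(candidates: Sequence, evaluations: Sequence[ConfusionMatrix],
                 variability_weight: float = 1.0) -> int:
    """Index of the best candidate by accuracy minus interclass spread.

    Score = overall_accuracy - variability_weight * stdev(per-class
    accuracy); ties break toward the lower candidate index.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to select from")
    if len(candidates) != len(evaluations):
        raise ValueError("candidates and evaluations must align")
    best, best_score = 0, -np.inf
    for i, cm in enumerate(evaluations):
        per_class = cm.per_class_accuracy.dropna().to_numpy()
        spread = float(np.std(per_class)) if per_class.size else 0.0
        score = cm.overall_accuracy - variability_weight * spread
        if score > best_score:
            best, best_score = i, score
    return best


@dataclass
class MixtureBiasCurve:
    """Predicted vs true class proportions across constructed mixtures."""

    true_proportions: list
    predicted_proportions: list
    positive_class: str = ""

    def __post_init__(self) -> None:
        if len(self.true_proportions) != len(self.predicted_proportions):
            raise ValueError("proportion lists must align")
        for p in list(self.true_proportions) + list(self.predicted_proportions):
            if not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")

    @property
    def bias(self) -> list:
        return [p - t for t, p in
                zip(self.true_proportions, self.predicted_proportions)]


def quantify_bias(
    predict: Callable,
    mixtures: Sequence[tuple],
    positive_class,
) -> MixtureBiasCurve:
    """Estimate proportion bias of a classifier on constructed mixtures.

    Parameters
    ----------
    predict : callable
        Maps a batch of samples to predicted labels.
    mixtures : sequence of (true_proportion, samples)
        ``true_proportion`` is the fraction of ``positive_class`` items
        in ``samples``; samples must be independent of any training or
        test data.
    """
    true_props, pred_props = [], []
    for true_p, samples in mixtures:
        if len(samples) == 0:
            raise ValueError("empty mixture sample")
        pred = np.asarray(predict(samples))
        true_props.append(float(true_p))
        pred_props.append(float(np.mean(pred == positive_class)))
    return MixtureBiasCurve(true_props, pred_props, positive_class=str(positive_class))


def correct_bias(
    predicted_proportions: Sequence[float], confusion_rates: np.ndarray
) -> np.ndarray:
    """Invert classifier confusion to recover true class proportions.

    With ``confusion_rates[i, j] = P(predicted j | true i)``, observed
    proportions obey ``q = C^T p``.  The relation is inverted by
    nonnegative least squares and renormalized to sum to 1.
    """
    q = np.asarray(predicted_proportions, dtype=float)
    C = np.asarray(confusion_rates, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != q.size:
        raise ValueError("confusion matrix and proportions are inconsistent")
    if abs(np.linalg.det(C)) < 1e-12:
        raise ValueError("confusion matrix is singular; bias cannot be inverted")
    p, _ = nnls(C.T, q)
    total = p.sum()
    if total <= 0:
        raise ValueError("bias correction produced a degenerate solution")
    return p / total
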