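"""Multiclass classification and population-structure analysis.

Classification uses a gradient-boosted decision-tree ensemble (XGBoost),
which handles multiclass problems natively and weights its members
automatically. Accuracy is reported per class as the true positive rate
(TPR): the percentage of cells of a class predicted as that class, i.e. the
diagonal of the confusion matrix divided by its row sum.

Features are z-scored with training-set statistics before fitting — trees do
not require it, but the same standardisation feeds PCA and Ward clustering,
so all three analyses see identical inputs. Train and test sets are expected
to arrive as separate labelled tables (e.g. from separate wells); a seeded
stratified splitter is provided for synthetic work.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .errors import ParameterError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    """Hyperparameters of the boosted-tree ensemble."""

    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1
    seed: int = 0


@dataclass
class FittedModel:
    booster: XGBClassifier
    classes: list[str]
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    spec: ClassifierSpec

    def metadata(self) -> dict:
        return {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "n_estimators": self.spec.n_estimators,
            "max_depth": self.spec.max_depth,
            "learning_rate": self.spec.learning_rate,
            "seed": self.spec.seed,
        }


@dataclass
class ConfusionSummary:
    """Confusion counts plus per-class TPR percentages."""

    classes: list[str]
    matrix: np.ndarray  # true x predicted counts
    tpr: dict[str, float] = field(init=False)
    macro_tpr: float = field(init=False)

    def __post_init__(self) -> None:
        row_sums = self.matrix.sum(axis=1)
        diag = np.diag(self.matrix)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(row_sums > 0, 100.0 * diag / np.maximum(row_sums, 1), 0.0)
        self.tpr = {c: float(r) for c, r in zip(self.classes, rates)}
        self.macro_tpr = float(np.mean(rates))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)
        out.index.name = "true"
        out["TPR_percent"] = [self.tpr[c] for c in self.classes]
        return out


def _zscore_fit(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    mean = X.to_numpy(dtype=float).mean(axis=0)
    sd = X.to_numpy(dtype=float).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centred
    return mean, sd


def train_classifier(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    spec: ClassifierSpec | None = None,
) -> FittedModel:
    """Fit the multiclass boosted-tree model on z-scored features."""
    spec = spec or ClassifierSpec()
    y = np.asarray(y).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("training needs at least 2 classes")
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ParameterError(f"class(es) with < 2 training cells: {list(small)}")
    mean, sd = _zscore_fit(X)
    Z = (X.to_numpy(dtype=float) - mean) / sd
    encoded = np.searchsorted(classes, y)
    booster = XGBClassifier(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        random_state=spec.seed,
        n_jobs=1,
        verbosity=0,
    )
    booster.fit(Z, encoded)
    return FittedModel(
        booster=booster,
        classes=[str(c) for c in classes],
        feature_names=list(X.columns),
        scaler_mean=mean,
        scaler_sd=sd,
        spec=spec,
    )


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Class-label predictions; the feature schema must match training."""
    if list(X.columns) != model.feature_names:
        raise SchemaError("feature names do not match the training schema")
    Z = (X.to_numpy(dtype=float) - model.scaler_mean) / model.scaler_sd
    encoded = model.booster.predict(Z)
    return np.array(model.classes)[encoded]


def evaluate(model: FittedModel, X: pd.DataFrame, y: pd.Series | np.ndarray) -> ConfusionSummary:
    """Confusion matrix and per-class TPR on a labelled test table."""
    y = np.asarray(y).astype(str)
    unseen = set(y) - set(model.classes)
    if unseen:
        raise ParameterError(f"test classes unseen in training: {sorted(unseen)}")
    predicted = predict(model, X)
    k = len(model.classes)
    index = {c: i for i, c in enumerate(model.classes)}
    matrix = np.zeros((k, k), dtype=int)
    for t, p in zip(y, predicted):
        matrix[index[t], index[p]] += 1
    return ConfusionSummary(classes=model.classes, matrix=matrix)


def regroup_labels(
    y: pd.Series | np.ndarray, mapping: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Map class labels onto a coarser grouping.

    Returns (new labels, boolean keep-mask); cells of unmapped classes are
    dropped from the mask with a logged count.
    """
    y = np.asarray(y).astype(str)
    keep = np.array([label in mapping for label in y])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("regrouping drops %d cell(s) of unmapped class(es)", n_dropped)
    if not keep.any():
        raise ParameterError("regrouping dropped every cell")
    new = np.array([mapping.get(label, "") for label in y])
    return new[keep], keep


def hierarchical_clusters(X: pd.DataFrame, k: int) -> np.ndarray:
    """Agglomerative Ward clustering on z-scored features (deterministic)."""
    if k < 2:
        raise ParameterError("cluster count must be at least 2")
    if k > len(X):
        raise ParameterError(f"cannot form {k} clusters from {len(X)} cells")
    mean, sd = _zscore_fit(X)
    Z = (X.to_numpy(dtype=float) - mean) / sd
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(Z)


def pca_scores(
    X: pd.DataFrame, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA score coordinates on z-scored features.

    Zero-variance columns are dropped with a warning. Component signs are
    fixed by making each component's largest-magnitude loading positive, so
    repeated runs give identical score plots.
    Returns (scores, explained variance ratios).
    """
    if len(X) < 2:
        raise ParameterError("PCA needs at least 2 cells")
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0)
    drop = sd == 0
    if drop.any():
        logger.warning("PCA drops %d zero-variance column(s)", int(drop.sum()))
    values = values[:, ~drop]
    if values.shape[1] < n_components:
        raise ParameterError(
            f"only {values.shape[1]} varying features for {n_components} components"
        )
    Z = (values - values.mean(axis=0)) / values.std(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_


def stratified_split(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    test_size: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Seeded stratified train/test split utility."""
    y = np.asarray(y).astype(str)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    return X_train, X_test, y_train, y_test


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist the booster plus a JSON metadata sidecar."""
    path = Path(path)
    model.booster.get_booster().save_model(path)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(model.metadata(), indent=2)
    )
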