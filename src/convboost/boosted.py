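"""Gradient-boosted decision-tree classifier on feature matrices.

The ensemble is fit at library default hyperparameters — the point of the
hybrid approach is that no per-dataset tuning of the final classifier is
needed — with the seed pinned and the exact defaults snapshotted so that
library-version drift is detectable from the run log.  Binary problems use
the logistic objective, multiclass problems softmax over k classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb

from .extraction import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class TreeEnsembleModel:
    booster: xgb.XGBClassifier
    n_features: int
    classes: np.ndarray
    params: dict = field(default_factory=dict)


def _as_matrix(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.atleast_2d(np.asarray(fm, dtype=float))


def fit_trees(fm: FeatureMatrix | np.ndarray, y: np.ndarray, seed: int = 0,
              n_jobs: int = 1) -> TreeEnsembleModel:
    """Fit the boosted-tree ensemble at default hyperparameters.

    Requires at least two examples and two classes.  ``seed`` fixes the
    (already near-deterministic) tree construction; the resolved parameter
    set is logged for drift detection.
    """
    X = _as_matrix(fm)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 examples to fit")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("single-class input: need at least 2 classes to fit a classifier")
    clf = xgb.XGBClassifier(random_state=seed, n_jobs=n_jobs)
    clf.fit(X, y)
    params = clf.get_params()
    logger.info("fitted boosted trees on %d x %d features; params snapshot: %s",
                X.shape[0], X.shape[1], {k: v for k, v in sorted(params.items()) if v is not None})
    return TreeEnsembleModel(clf, n_features=X.shape[1], classes=classes, params=params)


def predict_labels(model: TreeEnsembleModel, fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = _as_matrix(fm)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    return model.booster.predict(X)


def evaluate_accuracy(model: TreeEnsembleModel, fm: FeatureMatrix | np.ndarray,
                      y: np.ndarray) -> float:
    """Fraction of correct predictions, in [0, 1]."""
    y = np.asarray(y)
    pred = predict_labels(model, fm)
    if pred.shape[0] != y.shape[0]:
        raise ValueError("rows of the feature matrix must align with y")
    return float((pred == y).mean())


def feature_importance(model: TreeEnsembleModel) -> list[tuple[int, float]]:
    """Features ranked by total information gain, non-increasing.

    Only features used in at least one split appear; indices refer to feature
    matrix columns and are traceable to layer coordinates through
    :meth:`FeatureMatrix.column_coordinate`.
    """
    score = model.booster.get_booster().get_score(importance_type="gain")
    ranked = sorted(((int(k[1:]), float(v)) for k, v in score.items()),
                    key=lambda kv: (-kv[1], kv[0]))
    return ranked


def save_model(model: TreeEnsembleModel, path: str) -> None:
    model.booster.save_model(path)


def importance_to_tsv(model: TreeEnsembleModel, fm: FeatureMatrix, path: str,
                      channels: int | None = None) -> None:
    """Export the ranked importance table as TSV (rank, feature_index, layer_coordinate, gain)."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature_index\tlayer_coordinate\tgain\n")
        for rank, (j, gain) in enumerate(feature_importance(model), start=1):
            fh.write(f"{rank}\t{j}\t{fm.column_coordinate(j, channels)}\t{gain:.6g}\n")
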