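"""Window-level classical classifiers.

Four model families are supported: Gaussian Naive Bayes, Random Forest
(100 trees, max_depth = 30), an RBF-kernel SVM, and XGBoost (100 boosting
rounds, max_depth = 30).  Scale-sensitive learners (NB, SVM) see z-scored
features using training-split statistics; tree models consume raw features.
Cost-sensitive training accepts a class-weight map for every family except
Naive Bayes, which has no concept of class weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import META_COLUMNS
from .prediction import PredictionStream

MODEL_FAMILIES = ("naive_bayes", "random_forest", "svm_rbf", "xgboost")


@dataclass
class ModelConfig:
    family: str = "xgboost"
    n_trees: int = 100
    max_depth: int = 30
    class_weights: dict[str, float] | None = None
    seed: int = 0
    svm_c: float = 1.0          # regularization; the study prints only the kernel
    svm_gamma: str | float = "scale"


@dataclass
class TrainedModel:
    """Fitted estimator plus the schema it was trained under."""

    estimator: object
    feature_columns: list[str]
    classes: list[str]
    scaler: StandardScaler | None = None
    metadata: dict = field(default_factory=dict)


def _feature_frame(features: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in features.columns if c not in META_COLUMNS]
    return features[cols]


def train(features: pd.DataFrame, cfg: ModelConfig) -> TrainedModel:
    """Fit a window-level classifier on a feature matrix with a ``label`` column."""
    if cfg.family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {cfg.family!r}")
    X_df = _feature_frame(features)
    X = X_df.to_numpy(dtype=float)
    y = features["label"].to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in training data")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training set contains a single class")

    scaler = None
    cw = cfg.class_weights
    if cfg.family == "naive_bayes":
        if cw is not None:
            raise ValueError("Naive Bayes has no concept of class weights")
        scaler = StandardScaler().fit(X)
        est = GaussianNB().fit(scaler.transform(X), y)
    elif cfg.family == "svm_rbf":
        scaler = StandardScaler().fit(X)
        est = SVC(
            kernel="rbf",
            C=cfg.svm_c,
            gamma=cfg.svm_gamma,
            class_weight=cw,
            random_state=cfg.seed,
        ).fit(scaler.transform(X), y)
    elif cfg.family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            class_weight=cw,
            random_state=cfg.seed,
            n_jobs=1,
        ).fit(X, y)
    else:  # xgboost
        from xgboost import XGBClassifier

        codes = np.searchsorted(classes, y)
        sample_weight = None
        if cw is not None:
            sample_weight = np.array([cw[lab] for lab in y])
        est = XGBClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            random_state=cfg.seed,
            tree_method="hist",
            max_bin=64,
            n_jobs=1,
            verbosity=0,
        )
        est.fit(X, codes, sample_weight=sample_weight)

    return TrainedModel(
        estimator=est,
        feature_columns=list(X_df.columns),
        classes=classes,
        scaler=scaler,
        metadata={"family": cfg.family, "seed": cfg.seed,
                  "class_weights": cw is not None},
    )


def predict_stream(model: TrainedModel, features: pd.DataFrame) -> PredictionStream:
    """Predict one label per feature row, in window time order.

    The stride is inferred from consecutive window anchors.  Raises on a
    feature-schema mismatch.
    """
    X_df = _feature_frame(features)
    if list(X_df.columns) != model.feature_columns:
        raise ValueError("feature schema does not match the trained model")
    X = X_df.to_numpy(dtype=float)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    raw = model.estimator.predict(X)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        labels = np.asarray([model.classes[int(i)] for i in raw], dtype=object)
    else:
        labels = np.asarray(raw, dtype=object)
    starts = features["window_start_s"].to_numpy()
    diffs = np.diff(starts)
    diffs = diffs[diffs > 0]
    stride = float(np.median(diffs)) if len(diffs) else 0.25
    return PredictionStream(labels, stride)
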