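"""Confidence-regression and direction-classification models.

The reference backend is a non-tweaked random forest (500 trees, library
defaults otherwise, no hyperparameter search) — deliberately plain, because
the object of study is the train/validation layout, not the learner.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .features import FeatureMatrix


class ModelError(ValueError):
    pass


class Task(str, Enum):
    CONFIDENCE_REGRESSION = "confidence_regression"
    DIRECTION_CLASSIFICATION = "direction_classification"


@dataclass
class ModelSpec:
    task: Task = Task.CONFIDENCE_REGRESSION
    n_estimators: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.n_estimators < 1:
            raise ModelError("n_estimators must be >= 1")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    estimator: object
    training_hash: str = ""


@dataclass
class PredictionSet:
    """Predictions aligned with ``snv_index``.

    ``predicted_confidence`` is clipped to [0, 1].  For the direction task,
    ``predicted_direction_score`` is the expected class value
    sum_k k * P(class k) over k in {-1, 0, 1} and the label is the argmax
    class.
    """

    snv_index: list[str]
    predicted_confidence: np.ndarray | None = None
    predicted_direction_score: np.ndarray | None = None
    predicted_direction_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.snv_index)
        for arr in (self.predicted_confidence, self.predicted_direction_score,
                    self.predicted_direction_label):
            if arr is not None and len(arr) != n:
                raise ModelError("prediction arrays misaligned with snv_index")


def _training_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(features: FeatureMatrix, targets: np.ndarray, spec: ModelSpec) -> FittedModel:
    """Fit the model on training rows only.  Deterministic given the seed."""
    X = features.values
    y = np.asarray(targets)
    if X.shape[0] == 0:
        raise ModelError("empty training set")
    if X.shape[0] != len(y):
        raise ModelError(
            f"feature rows ({X.shape[0]}) do not match targets ({len(y)})"
        )
    if X.shape[1] == 0:
        raise ModelError("feature matrix has zero columns")
    if spec.task == Task.CONFIDENCE_REGRESSION:
        est = RandomForestRegressor(
            n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
        )
    else:
        classes = np.unique(y)
        if len(classes) < 2:
            raise ModelError(
                f"direction training set is degenerate: only class "
                f"{int(classes[0])} present"
            )
        est = RandomForestClassifier(
            n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
        )
    est.fit(X, y)
    return FittedModel(
        spec=spec,
        feature_names=features.feature_names,
        estimator=est,
        training_hash=_training_hash(X, y),
    )


def predict(model: FittedModel, features: FeatureMatrix) -> PredictionSet:
    if features.feature_names != model.feature_names:
        missing = set(model.feature_names) - set(features.feature_names)
        extra = set(features.feature_names) - set(model.feature_names)
        raise ModelError(
            f"feature columns differ from training: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    X = features.values
    if model.spec.task == Task.CONFIDENCE_REGRESSION:
        raw = model.estimator.predict(X)
        return PredictionSet(
            snv_index=features.snv_index,
            predicted_confidence=np.clip(raw, 0.0, 1.0),
        )
    proba = model.estimator.predict_proba(X)
    classes = np.asarray(model.estimator.classes_, dtype=float)
    score = proba @ classes
    label = classes[np.argmax(proba, axis=1)].astype(int)
    return PredictionSet(
        snv_index=features.snv_index,
        predicted_direction_score=score,
        predicted_direction_label=label,
    )


def binary_scores(prediction_set: PredictionSet) -> np.ndarray:
    """Threshold-free ranking scores for regulatory-vs-neutral: the predicted
    confidence itself."""
    if prediction_set.predicted_confidence is None:
        raise ModelError("prediction set carries no predicted confidence")
    return np.asarray(prediction_set.predicted_confidence)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist the estimator blob next to a JSON manifest."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    manifest = {
        "task": model.spec.task.value,
        "n_estimators": model.spec.n_estimators,
        "seed": model.spec.seed,
        "feature_names": model.feature_names,
        "training_hash": model.training_hash,
        "format_version": 1,
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text()
    )
    if manifest.get("format_version") != 1:
        raise ModelError(f"unsupported model format {manifest.get('format_version')}")
    est = joblib.load(path)
    return FittedModel(
        spec=ModelSpec(task=manifest["task"], n_estimators=manifest["n_estimators"],
                       seed=manifest["seed"]),
        feature_names=list(manifest["feature_names"]),
        estimator=est,
        training_hash=manifest["training_hash"],
    )
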