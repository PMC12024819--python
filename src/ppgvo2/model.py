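"""Bagged regression-tree ensemble mapping (m1, m2, height, weight) to VO2.

Each tree is fitted on a bootstrap resample (with replacement, same size as
the training set) and the ensemble prediction is the arithmetic mean of the
trees' outputs.  With only four features no per-split feature subsampling is
used, so the ensemble is plain bagging.  Fitting delegates to scikit-learn's
forest machinery (``max_features=1.0``, ``bootstrap=True``); the contract —
bootstrap resampling, mean aggregation, seed determinism — is what the test
suite asserts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from . import __version__

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMN",
    "ModelConfig",
    "EnsembleModel",
    "EvalReport",
    "train",
    "predict",
    "evaluate",
    "split_pooled_random",
    "split_leave_one_subject_out",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS: tuple[str, ...] = ("m1", "m2", "height_cm", "weight_kg")
TARGET_COLUMN = "vo2_ref"


@dataclass(frozen=True)
class ModelConfig:
    """Ensemble hyperparameters; defaults are deliberately plain."""

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 2
    seed: int = 0


@dataclass
class EnsembleModel:
    """A fitted bagged-tree ensemble with its feature schema and provenance."""

    forest: RandomForestRegressor
    feature_names: tuple[str, ...]
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    @property
    def trees(self) -> list:
        return list(self.forest.estimators_)


def _feature_matrix(features: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    x = features.loc[:, list(names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.unique(np.nonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite feature values in rows {bad[:10].tolist()}")
    return x


def train(
    features: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    feature_names: Sequence[str] = FEATURE_COLUMNS,
    target: str = TARGET_COLUMN,
) -> EnsembleModel:
    """Fit the ensemble on a feature table that includes reference targets."""
    if target not in features.columns:
        raise ValueError(f"feature table has no target column {target!r}")
    y = features[target].to_numpy(dtype=float)
    if y.size < 2:
        raise ValueError(f"need at least 2 training rows, got {y.size}")
    if not np.all(np.isfinite(y)):
        bad = np.flatnonzero(~np.isfinite(y))
        raise ValueError(f"non-finite targets in rows {bad[:10].tolist()}")
    x = _feature_matrix(features, feature_names)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        max_features=1.0,      # consider all features at every split: pure bagging
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    meta = {
        "n_rows": int(y.size),
        "feature_names": list(feature_names),
        "package_version": __version__,
    }
    return EnsembleModel(
        forest=forest,
        feature_names=tuple(feature_names),
        config=config,
        metadata=meta,
    )


def predict(model: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    """Mean-over-trees VO2 prediction (mL/kg/min) for each feature row.

    The feature table must carry exactly the training schema's columns
    (extra unrelated columns are tolerated; they are simply not used).
    """
    x = _feature_matrix(features, model.feature_names)
    return model.forest.predict(x)


@dataclass
class EvalReport:
    """Held-out accuracy summary: MAE, R^2 and the per-row residual table."""

    mae: float
    r2: float
    residuals: pd.DataFrame  # columns: predicted, actual, residual
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "r2": self.r2, "n": self.n}


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """MAE and coefficient of determination with residuals for export.

    R^2 = 1 - SS_res / SS_tot; undefined (error) when the actuals have zero
    variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty 1-D arrays")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: zero variance in y_true")
    resid = y_true - y_pred
    mae = float(np.abs(resid).mean())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    table = pd.DataFrame({"predicted": y_pred, "actual": y_true, "residual": resid})
    return EvalReport(mae=mae, r2=r2, residuals=table, n=y_true.size)


def split_pooled_random(
    features: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition windows uniformly at random into train/test.

    ``fraction`` is the training share; the training size is
    floor(fraction * n).  Subjects are shared across the two sides, which
    mirrors a pooled residual analysis and is optimistic relative to
    leave-one-subject-out.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(features)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    train_df = features.iloc[order[:n_train]].reset_index(drop=True)
    test_df = features.iloc[order[n_train:]].reset_index(drop=True)
    return train_df, test_df


def split_leave_one_subject_out(
    features: pd.DataFrame,
) -> Iterator[tuple[str, pd.DataFrame, pd.DataFrame]]:
    """Yield (held-out subject, train, test) folds, one per subject."""
    if "subject_id" not in features.columns:
        raise ValueError("feature table has no subject_id column")
    for sid in pd.unique(features["subject_id"]):
        mask = features["subject_id"] == sid
        yield str(sid), features[~mask].reset_index(drop=True), features[mask].reset_index(drop=True)


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist the fitted ensemble (joblib blob + JSON sidecar metadata)."""
    path = Path(path)
    joblib.dump({"forest": model.forest, "feature_names": model.feature_names,
                 "config": asdict(model.config)}, path)
    sidecar = {
        "feature_names": list(model.feature_names),
        "config": asdict(model.config),
        "metadata": model.metadata,
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )


def load_model(path: str | Path) -> EnsembleModel:
    """Load a persisted ensemble; predictions round-trip bit-exactly."""
    path = Path(path)
    try:
        blob = joblib.load(path)
        forest = blob["forest"]
        feature_names = tuple(blob["feature_names"])
        config = ModelConfig(**blob["config"])
    except Exception as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    metadata = {}
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        metadata = sidecar.get("metadata", {})
        saved_version = sidecar.get("package_version")
        if saved_version != __version__:
            warnings.warn(
                f"model saved with package version {saved_version}, "
                f"loading under {__version__}",
                stacklevel=2,
            )
    return EnsembleModel(forest=forest, feature_names=feature_names,
                         config=config, metadata=metadata)
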