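"""End-to-end orchestration: simulate -> features -> split -> train -> evaluate.

One seed fans out (via hashed sub-seeds) to calibration synthesis, cohort
generation, the train/test split and the ensemble's bootstrap draws, so a
whole experiment is reproducible from a single integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._seeds import derive_seed
from .calibration import CalibrationTable, make_default_calibration
from .features import build_feature_table, window_slopes
from .model import (
    EnsembleModel,
    EvalReport,
    ModelConfig,
    evaluate,
    predict,
    split_leave_one_subject_out,
    split_pooled_random,
    train,
)
from .simulate import DEFAULT_PROTOCOL, CohortMember, ProtocolSpec, generate_cohort

__all__ = ["ExperimentResult", "cohort_features", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentResult:
    """Everything one synthetic-cohort experiment produced."""

    report: EvalReport
    model: EnsembleModel
    features: pd.DataFrame
    train_rows: int
    test_rows: int
    loso_reports: dict[str, EvalReport] = field(default_factory=dict)


def cohort_features(
    members: Sequence[CohortMember],
    calib: CalibrationTable,
    wavelengths: Sequence[int] | None = None,
    window_s: float = 10.0,
) -> pd.DataFrame:
    """Slope features + anthropometrics + aligned reference VO2, all subjects."""
    anthropometrics = {m.subject.subject_id: m.meta for m in members}
    tables = []
    for m in members:
        slopes = window_slopes(m.record, calib, wavelength_subset=wavelengths, window_s=window_s)
        tables.append(
            build_feature_table(
                slopes, m.record.subject_id, anthropometrics, m.vo2_ref, window_s=window_s
            )
        )
    return pd.concat(tables, ignore_index=True)


def run_experiment(
    seed: int = 42,
    n_subjects: int = 8,
    wavelengths: Sequence[int] | None = None,
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    split: str = "pooled",
    train_fraction: float = 0.8,
    n_trees: int = 100,
    noise: bool = True,
    window_s: float = 10.0,
) -> ExperimentResult:
    """Simulate the default cohort, extract features, train and evaluate.

    ``split`` is ``"pooled"`` (random window split, ``train_fraction``
    training share) or ``"loso"`` (leave-one-subject-out; the returned
    report pools the per-fold held-out predictions and per-fold reports are
    kept alongside).
    """
    calib = make_default_calibration(derive_seed(seed, "calibration"))
    members = generate_cohort(
        n_subjects=n_subjects, protocol=protocol, seed=derive_seed(seed, "cohort"),
        calib=calib, noise=noise,
    )
    features = cohort_features(members, calib, wavelengths=wavelengths, window_s=window_s)
    config = ModelConfig(n_trees=n_trees, seed=derive_seed(seed, "model"))

    if split == "pooled":
        train_df, test_df = split_pooled_random(
            features, fraction=train_fraction, seed=derive_seed(seed, "split")
        )
        fitted = train(train_df, config)
        report = evaluate(test_df["vo2_ref"].to_numpy(), predict(fitted, test_df))
        return ExperimentResult(
            report=report, model=fitted, features=features,
            train_rows=len(train_df), test_rows=len(test_df),
        )
    if split == "loso":
        loso_reports: dict[str, EvalReport] = {}
        pooled_true, pooled_pred = [], []
        fitted = None
        for sid, train_df, test_df in split_leave_one_subject_out(features):
            fitted = train(train_df, config)
            pred = predict(fitted, test_df)
            loso_reports[sid] = evaluate(test_df["vo2_ref"].to_numpy(), pred)
            pooled_true.append(test_df["vo2_ref"].to_numpy())
            pooled_pred.append(pred)
        import numpy as np

        report = evaluate(np.concatenate(pooled_true), np.concatenate(pooled_pred))
        full_model = train(features, config)
        return ExperimentResult(
            report=report, model=full_model, features=features,
            train_rows=len(features), test_rows=len(features),
            loso_reports=loso_reports,
        )
    raise ValueError(f"unknown split strategy {split!r} (expected 'pooled' or 'loso')")
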