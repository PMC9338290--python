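"""Dataset splitting, feature selection and the BP regression ensembles.

The SBP and DBP estimators are fixed, seeded heterogeneous ensembles of
tree-based regressors — a random forest, gradient-boosted trees and bagged
decision trees, averaged — trained on the impurity-selected features plus
demographics.  A demographics-only baseline is trained with identical
hyperparameters; comparing the two quantifies what the wearable's signals
add beyond age, sex, height and weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from .config import ModelConfig
from .feature_extraction import DEMOGRAPHIC_FEATURES, FEATURE_REGISTRY

TARGETS = ("sbp", "dbp")


def split_dataset(n_rows: int, fraction: float = 0.8, seed: int = 0,
                  subject_ids=None, level: str = "observation") -> np.ndarray:
    """Assign each row to "train" or "test".

    Observation-level (default): a seeded uniform permutation with exactly
    ``floor(fraction * n)`` training rows.  Subject-level: whole subjects are
    assigned by permuted cumulative count, the closest achievable to the
    target fraction (provided for leakage-sensitivity experiments).
    """
    if n_rows < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = int(np.floor(fraction * n_rows))
    rng = np.random.default_rng(seed)
    labels = np.empty(n_rows, dtype=object)
    if level == "observation":
        perm = rng.permutation(n_rows)
        labels[perm[:n_train]] = "train"
        labels[perm[n_train:]] = "test"
    elif level == "subject":
        if subject_ids is None:
            raise ValueError("subject-level split requires subject_ids")
        subject_ids = np.asarray(subject_ids)
        subjects = rng.permutation(pd.unique(subject_ids))
        labels[:] = "test"
        assigned = 0
        for s in subjects:
            size = int((subject_ids == s).sum())
            if abs(assigned + size - n_train) <= abs(assigned - n_train):
                labels[subject_ids == s] = "train"
                assigned += size
            if assigned >= n_train:
                break
    else:
        raise ValueError(f"unknown split level {level!r}")
    return labels


def select_features(X: pd.DataFrame, y, threshold: float = 0.02,
                    seed: int = 0, n_trees: int = 200) -> tuple[list[str], pd.Series]:
    """Impurity-importance feature selection.

    Fits a seeded random forest on all registry features, normalizes the
    impurity importances to sum to one, and keeps features whose relative
    importance exceeds ``threshold``.  Demographics compete on equal terms —
    eligible but never forced.  Returns (selected names, importance series).
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 50:
        raise ValueError("need at least 50 training rows for selection")
    if np.var(y) == 0:
        raise ValueError("degenerate target: zero variance")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Xv).any():  # median-impute so importances are well defined
        med = np.nanmedian(Xv, axis=0)
        idx = np.where(np.isnan(Xv))
        Xv[idx] = np.take(med, idx[1])
    rf.fit(Xv, y)
    imp = pd.Series(rf.feature_importances_, index=X.columns)
    imp = imp / imp.sum()
    selected = [c for c in X.columns if imp[c] > threshold]
    return selected, imp


@dataclass
class TrainedModel:
    """A fitted SBP or DBP ensemble with its preprocessing state."""

    target: str
    features: list[str]
    members: list = field(default_factory=list)
    medians: dict[str, float] = field(default_factory=dict)
    indicator_features: list[str] = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""

    def _matrix(self, rows: pd.DataFrame) -> np.ndarray:
        missing_cols = [f for f in self.features if f not in rows.columns]
        if missing_cols:
            raise KeyError(f"missing selected feature(s): {missing_cols}")
        cols = []
        for f in self.features:
            v = rows[f].astype(float).to_numpy().copy()
            nan = np.isnan(v)
            if nan.any():
                v[nan] = self.medians[f]
            cols.append(v)
        for f in self.indicator_features:
            v = rows[f].astype(float).to_numpy()
            cols.append(np.isnan(v).astype(float))
        return np.column_stack(cols)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Average of the member predictions; deterministic and finite."""
        X = self._matrix(rows)
        preds = np.mean([m.predict(X) for m in self.members], axis=0)
        return preds

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        return joblib.load(path)


def _fit_ensemble(X: np.ndarray, y: np.ndarray, seed: int,
                  config: ModelConfig) -> list:
    members = [
        RandomForestRegressor(n_estimators=config.n_rf, random_state=seed,
                              n_jobs=1),
        GradientBoostingRegressor(n_estimators=config.n_gbr,
                                  random_state=seed + 1),
        BaggingRegressor(estimator=DecisionTreeRegressor(random_state=seed + 2),
                         n_estimators=config.n_bag, random_state=seed + 3),
    ]
    for m in members:
        m.fit(X, y)
    return members


def train_model(train_df: pd.DataFrame, target: str, features: list[str],
                seed: int = 0, config: ModelConfig | None = None,
                config_hash: str = "") -> TrainedModel:
    """Train one target's ensemble on the given features.

    NaNs in selected feature columns are median-imputed (training medians)
    with companion missing-indicator columns for any feature that had
    missing values in training; a feature column that is entirely NaN is a
    training error.
    """
    config = config or ModelConfig()
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}")
    y = train_df[f"{target}_ref"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("NaN in target column")

    model = TrainedModel(target=target, features=list(features), seed=seed,
                         config_hash=config_hash)
    for f in features:
        v = train_df[f].astype(float)
        if v.isna().all():
            raise ValueError(f"feature {f!r} has no observed values")
        model.medians[f] = float(v.median())
        if v.isna().any():
            model.indicator_features.append(f)
    X = model._matrix(train_df)
    model.members = _fit_ensemble(X, y, seed, config)
    return model


def train_models(train_df: pd.DataFrame, selected: dict[str, list[str]],
                 seed: int = 0, config: ModelConfig | None = None,
                 config_hash: str = "") -> dict[str, TrainedModel]:
    """Train the SBP and DBP signal models (selected features per target)."""
    return {
        t: train_model(train_df, t, selected[t], seed=seed + i,
                       config=config, config_hash=config_hash)
        for i, t in enumerate(TARGETS)
    }


def train_baseline(train_df: pd.DataFrame, seed: int = 0,
                   config: ModelConfig | None = None,
                   config_hash: str = "") -> dict[str, TrainedModel]:
    """Demographics-only reference models, same procedure and hyperparameters."""
    return {
        t: train_model(train_df, t, list(DEMOGRAPHIC_FEATURES), seed=seed + i,
                       config=config, config_hash=config_hash)
        for i, t in enumerate(TARGETS)
    }


def registry_features(df: pd.DataFrame) -> list[str]:
    """Registry feature columns present in a feature matrix."""
    return [c for c in FEATURE_REGISTRY if c in df.columns]
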