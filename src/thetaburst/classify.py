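"""Condition prediction from per-burst features with a gradient-boosted tree
ensemble.

Evaluation is grouped cross-validation by default: all bursts from one
subject stay in the same fold, so the reported AUC reflects generalisation
to unseen animals rather than within-animal memorisation.  Normalisation
(z-score) and median imputation are fit on the training folds only.
Hyperparameters are fixed (depth 4, 200 trees, learning rate 0.1); tuning
is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from xgboost import XGBClassifier

__all__ = ["FeatureTable", "ClassifierReport", "build_table", "train_eval"]

META_COLS = ("subject_id", "session_id", "condition")


@dataclass
class FeatureTable:
    """Per-burst features plus grouping metadata (never fed to the model)."""

    data: pd.DataFrame
    feature_cols: list[str]
    label_col: str = "condition"
    group_col: str = "subject_id"
    positive_label: str = "etoh"
    dropped: list[str] = field(default_factory=list)


@dataclass
class ClassifierReport:
    roc_auc: float
    average_precision: float
    accuracy: float
    confusion: np.ndarray  # row-normalised, rows = true class (neg, pos)
    per_class: dict[str, dict[str, float]]
    oof_probabilities: pd.DataFrame
    feature_importances: pd.Series
    prob_hist: dict[str, np.ndarray]
    hist_edges: np.ndarray


def build_table(events_by_session: dict[str, pd.DataFrame], positive_label: str = "etoh") -> FeatureTable:
    """Assemble per-burst rows from per-session feature frames.

    Each value of ``events_by_session`` must carry ``subject_id`` and
    ``condition`` columns plus numeric feature columns.  Constant features
    are dropped with a warning; subject/session identifiers are retained for
    grouping but excluded from model inputs.
    """
    frames = []
    for session_id, df in events_by_session.items():
        df = df.copy()
        df["session_id"] = session_id
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    if data["condition"].nunique() < 2:
        raise ValueError("feature table spans a single condition; nothing to classify")
    feature_cols = [
        c for c in data.columns
        if c not in META_COLS and c != "session_id" and pd.api.types.is_numeric_dtype(data[c])
    ]
    dropped = [c for c in feature_cols if data[c].nunique(dropna=True) <= 1]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        feature_cols = [c for c in feature_cols if c not in dropped]
    return FeatureTable(data=data, feature_cols=feature_cols, positive_label=positive_label, dropped=dropped)


def train_eval(
    table: FeatureTable,
    folds: int = 5,
    grouped: bool = True,
    seed: int = 0,
    threshold: float = 0.5,
) -> ClassifierReport:
    """Cross-validated XGBoost evaluation with pooled out-of-fold predictions.

    With ``grouped=True`` folds are stratified by label but never split a
    subject across train and test; ``grouped=False`` pools bursts (an
    optimistic comparison mode).  Deterministic given ``seed`` and the table.
    """
    df = table.data
    y = (df[table.label_col] == table.positive_label).to_numpy(dtype=int)
    X = df[table.feature_cols].to_numpy(dtype=float)
    groups = df[table.group_col].to_numpy()

    if grouped:
        n_groups = len(np.unique(groups))
        splitter = StratifiedGroupKFold(n_splits=min(folds, n_groups), shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)

    oof = np.full(len(y), np.nan)
    importances = np.zeros(len(table.feature_cols))
    n_models = 0
    for train_idx, test_idx in split_iter:
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("a fold lacks both classes; re-stratify or supply more sessions")
        med = np.nanmedian(X[train_idx], axis=0)
        Xtr = np.where(np.isnan(X[train_idx]), med, X[train_idx])
        Xte = np.where(np.isnan(X[test_idx]), med, X[test_idx])
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        model = XGBClassifier(
            max_depth=4,
            n_estimators=200,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
        )
        model.fit(Xtr, y[train_idx])
        oof[test_idx] = model.predict_proba(Xte)[:, 1]
        importances += model.feature_importances_
        n_models += 1

    valid = ~np.isnan(oof)
    y_v, p_v = y[valid], oof[valid]
    pred = (p_v >= threshold).astype(int)
    cm = confusion_matrix(y_v, pred, labels=[0, 1]).astype(float)
    cm_norm = cm / np.clip(cm.sum(axis=1, keepdims=True), 1, None)
    acc = float((pred == y_v).mean())
    per_class = {}
    for label, cls in (("saline", 0), (table.positive_label, 1)):
        tp = np.sum((pred == cls) & (y_v == cls))
        per_class[label] = {
            "precision": float(tp / max(np.sum(pred == cls), 1)),
            "recall": float(tp / max(np.sum(y_v == cls), 1)),
        }
    edges = np.linspace(0, 1, 21)
    hist = {
        "saline": np.histogram(p_v[y_v == 0], bins=edges)[0],
        table.positive_label: np.histogram(p_v[y_v == 1], bins=edges)[0],
    }
    oof_df = df.loc[valid, ["subject_id", "session_id", "condition"]].copy()
    oof_df["probability"] = p_v
    return ClassifierReport(
        roc_auc=float(roc_auc_score(y_v, p_v)),
        average_precision=float(average_precision_score(y_v, p_v)),
        accuracy=acc,
        confusion=cm_norm,
        per_class=per_class,
        oof_probabilities=oof_df,
        feature_importances=pd.Series(importances / max(n_models, 1), index=table.feature_cols).sort_values(ascending=False),
        prob_hist=hist,
        hist_edges=edges,
    )
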