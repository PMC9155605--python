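"""Supervised model training, selection and evaluation for SAR endpoints.

Implements the validation protocol used throughout: stratified 10-fold
cross-validation with pooled out-of-fold metrics, random 10% blind tests,
random-forest defaults (300 trees), stepwise forward greedy feature
selection, and Fisher r-to-z comparison of correlation coefficients.

Pooled metrics (one metric on the out-of-fold prediction vector) are the
headline numbers; per-fold values are reported alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .chem import ContractError, DatasetError, MoleculeRecord
from .signatures import DEFAULT_CUTOFFS, featurize_smiles

logger = logging.getLogger("herbsig")

_CLASSIFIERS = {
    "random_forest": RandomForestClassifier,
    "extra_trees": ExtraTreesClassifier,
    "gradient_boosting": GradientBoostingClassifier,
    "logistic_regression": LogisticRegression,
}
_REGRESSORS = {
    "random_forest": RandomForestRegressor,
    "extra_trees": ExtraTreesRegressor,
    "gradient_boosting": GradientBoostingRegressor,
    "ridge": Ridge,
}


@dataclass
class ModelSpec:
    """Serialisable description of a model: task, algorithm, settings, seed."""

    task: str  # "classification" | "regression"
    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=lambda: {"n_estimators": 300})
    seed: int = 0
    selected_features: Optional[list[str]] = None

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ContractError(f"unknown task {self.task!r}")
        registry = _CLASSIFIERS if self.task == "classification" else _REGRESSORS
        if self.algorithm not in registry:
            raise ContractError(
                f"unknown {self.task} algorithm {self.algorithm!r} "
                f"(available: {sorted(registry)})"
            )

    def make_estimator(self):
        registry = _CLASSIFIERS if self.task == "classification" else _REGRESSORS
        cls = registry[self.algorithm]
        kwargs = dict(self.hyperparameters)
        if "random_state" in cls().get_params():
            kwargs.setdefault("random_state", self.seed)
        return cls(**kwargs)


@dataclass
class EvaluationReport:
    """Metrics for one evaluation: pooled values plus optional per-fold."""

    task: str
    protocol: str  # "cross-validation" | "blind test" | "direct"
    metrics: dict[str, float]
    per_fold: Optional[list[dict[str, float]]] = None
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": "pooled", **self.metrics}]
        for k, fm in enumerate(self.per_fold or []):
            rows.append({"fold": k, **fm})
        return pd.DataFrame(rows)


# --- splits ---------------------------------------------------------------

def stratified_kfold_split(
    labels: Sequence[int], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds (0..k-1)."""
    y = np.asarray(labels)
    if k < 2:
        raise ContractError("k must be >= 2")
    if len(y) < k:
        raise ContractError(f"n={len(y)} smaller than k={k}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DatasetError("stratification requires both classes present")
    if counts.min() < k:
        raise DatasetError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} members, "
            f"fewer than k={k} folds"
        )
    assignment = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def blind_split(
    records: Sequence, fraction: float = 0.10, seed: int = 0, stratify=None
) -> tuple[list, list]:
    """Random held-out split: ``round(fraction * n)`` records held out.

    Simple random by default; pass per-record labels as ``stratify`` for a
    stratified variant.
    """
    n = len(records)
    if not 0 < fraction < 1:
        raise ContractError("fraction must be in (0, 1)")
    n_test = int(np.floor(fraction * n + 0.5))
    if n_test == 0 or n_test == n:
        raise ContractError(f"fraction {fraction} yields a degenerate split of n={n}")
    rng = np.random.default_rng(seed)
    if stratify is None:
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
    else:
        y = np.asarray(stratify)
        test_idx = set()
        # proportional allocation per class, remainders to largest classes
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            take = int(np.floor(fraction * len(members) + 0.5))
            test_idx.update(rng.permutation(members)[:take].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


# --- training & evaluation ------------------------------------------------

def _as_matrix(X) -> np.ndarray:
    return X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def train_model(X, y, spec: ModelSpec):
    """Fit the estimator described by ``spec``; deterministic under its seed."""
    Xm, ya = _as_matrix(X), np.asarray(y)
    if Xm.shape[0] != len(ya):
        raise ContractError(f"X has {Xm.shape[0]} rows but y has {len(ya)}")
    if np.isnan(Xm).any():
        raise ContractError("X contains missing values")
    if spec.task == "classification" and len(np.unique(ya)) < 2:
        raise ContractError("classification training set has a single class")
    est = spec.make_estimator()
    est.fit(Xm, ya)
    return est


def _positive_scores(est, Xm: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(Xm)
    return proba[:, list(est.classes_).index(1)]


def evaluate_classification(
    y_true, scores, threshold: float = 0.5, protocol: str = "direct"
) -> EvaluationReport:
    """Threshold metrics plus ROC-AUC (rank) and PR-AUC (integration)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ContractError("y_true and scores differ in length")
    if s.min() < 0 or s.max() > 1:
        raise ContractError("scores must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise DatasetError("AUC undefined: only one class present")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    metrics = {
        "accuracy": (tp + tn) / len(y),
        "mcc": ((tp * tn - fp * fn) / mcc_den) if mcc_den > 0 else 0.0,
        "roc_auc": float(roc_auc_score(y, s)),
        "pr_auc": float(average_precision_score(y, s)),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    return EvaluationReport("classification", protocol, metrics, n=len(y))


def evaluate_regression(
    y_true, y_pred, trim_fraction: float = 0.10, protocol: str = "direct"
) -> EvaluationReport:
    """Pearson r and RMSE, plus r after trimming the worst-predicted points.

    The trimmed value removes the ``round(trim_fraction * n)`` largest
    absolute residuals before recomputing r — a reporting device only, the
    predictions themselves are untouched.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) != len(p):
        raise ContractError("y_true and y_pred differ in length")
    if len(y) < 3:
        raise ContractError("need at least 3 points")
    if np.std(y) == 0 or np.std(p) == 0:
        raise DatasetError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(y, p).statistic)
    rmse = float(np.sqrt(np.mean((y - p) ** 2)))
    n_trim = int(np.floor(trim_fraction * len(y) + 0.5))
    if n_trim > 0 and len(y) - n_trim >= 3:
        keep = np.argsort(-np.abs(y - p))[n_trim:]
        yk, pk = y[keep], p[keep]
        if np.std(yk) > 0 and np.std(pk) > 0:
            r_trim = float(stats.pearsonr(yk, pk).statistic)
        else:
            r_trim = float("nan")
    else:
        r_trim = r
    metrics = {
        "pearson_r": r,
        "rmse": rmse,
        "trimmed_pearson_r": r_trim,
        "n_trimmed": float(n_trim),
    }
    return EvaluationReport("regression", protocol, metrics, n=len(y))


def fisher_r_to_z_compare(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Compare two Pearson correlations via the Fisher r-to-z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the two-sided p
    comes from the standard normal.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ContractError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ContractError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --- cross-validation -----------------------------------------------------

def cross_validate(
    X,
    y,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    select_features: bool = False,
    selection_tolerance: float = 1e-3,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled out-of-fold metrics.

    Each sample is predicted exactly once, out of fold; the headline metric
    is computed once on the pooled prediction vector, with per-fold values
    reported alongside. When ``select_features`` is on, greedy forward
    selection runs inside each training fold (never on its test fold).
    """
    Xm, ya = _as_matrix(X), np.asarray(y)
    if spec.task == "classification":
        folds = stratified_kfold_split(ya, k=k, seed=seed)
    else:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(np.arange(len(ya)) % k)
    oof = np.full(len(ya), np.nan)
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        cols = np.arange(Xm.shape[1])
        Xtr = Xm[train]
        if select_features:
            sel = greedy_forward_selection(
                Xtr, ya[train], spec, tolerance=selection_tolerance, seed=seed
            )
            cols = np.asarray(sel, dtype=int)
            Xtr = Xtr[:, cols]
        est = train_model(Xtr, ya[train], spec)
        if spec.task == "classification":
            scores = _positive_scores(est, Xm[test][:, cols])
            fold_rep = evaluate_classification(ya[test], scores, threshold)
        else:
            scores = est.predict(Xm[test][:, cols])
            fold_rep = evaluate_regression(ya[test], scores)
        oof[test] = scores
        per_fold.append(fold_rep.metrics)
    assert not np.isnan(oof).any(), "every sample must be predicted exactly once"
    if spec.task == "classification":
        pooled = evaluate_classification(ya, oof, threshold, protocol="cross-validation")
    else:
        pooled = evaluate_regression(ya, oof, protocol="cross-validation")
    pooled.per_fold = per_fold
    pooled.predictions = oof  # out-of-fold scores, aligned with y
    return pooled


def _cv_metric(X, y, spec: ModelSpec, k: int, seed: int) -> float:
    """Pooled CV score used by the feature selector (AUC / Pearson r)."""
    rep = cross_validate(X, y, spec, k=k, seed=seed)
    return rep.metrics["roc_auc" if spec.task == "classification" else "pearson_r"]


def greedy_forward_selection(
    X,
    y,
    spec: ModelSpec,
    metric: Optional[Callable] = None,
    tolerance: float = 1e-3,
    k: int = 5,
    seed: int = 0,
    max_features: Optional[int] = None,
) -> list[int]:
    """Stepwise forward greedy feature selection.

    Starts empty and repeatedly adds the feature whose addition maximises
    the cross-validated metric (pooled ROC-AUC for classification, Pearson
    r for regression, or a user metric ``f(X, y, spec, k, seed)``),
    breaking ties toward the lower column index; stops when the best
    improvement is <= ``tolerance``. Returns selected column indices in
    order of addition.
    """
    Xm, ya = _as_matrix(X), np.asarray(y)
    if Xm.shape[1] < 2:
        raise ContractError("need at least 2 features to select from")
    score_fn = metric or _cv_metric
    selected: list[int] = []
    current = -np.inf
    limit = max_features or Xm.shape[1]
    while len(selected) < limit:
        best_j, best_score = None, -np.inf
        for j in range(Xm.shape[1]):
            if j in selected:
                continue
            trial = Xm[:, selected + [j]]
            if trial.std(axis=0).min() == 0:
                continue  # constant column adds nothing and breaks some metrics
            try:
                sc = score_fn(trial, ya, spec, k, seed)
            except (DatasetError, ContractError):
                continue
            if sc > best_score:  # strict: ties keep the lower index
                best_j, best_score = j, sc
        if best_j is None:
            break
        if selected and best_score - current <= tolerance:
            break
        selected.append(best_j)
        current = best_score
    return selected


# --- prediction profiles & persistence ------------------------------------

@dataclass
class EndpointModel:
    """A trained endpoint model plus the featurization it expects."""

    name: str
    spec: ModelSpec
    estimator: object
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    normalise: bool = False
    feature_names: Optional[list[str]] = None


def predict_profile(
    records: Sequence[MoleculeRecord],
    registry: dict[str, EndpointModel],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Predict every registered endpoint for every record.

    Classification endpoints yield ``<name>_class`` and ``<name>_prob``
    columns, regression endpoints ``<name>_value``. A molecule that cannot
    be featurized keeps its row with empty endpoint fields.
    """
    rows: list[dict] = []
    for rec in records:
        row: dict = {}
        feats: dict[tuple, np.ndarray] = {}
        try:
            for em in registry.values():
                key = (em.cutoffs, em.normalise)
                if key not in feats:
                    feats[key] = featurize_smiles(
                        rec.smiles, cutoffs=em.cutoffs, normalise=em.normalise
                    )
        except Exception as exc:  # malformed molecule: keep row, empty fields
            logger.warning("could not featurize %s: %s", rec.id, exc)
            rows.append(row)
            continue
        for name, em in registry.items():
            x = feats[(em.cutoffs, em.normalise)].reshape(1, -1)
            if em.spec.selected_features is not None and em.feature_names:
                idx = [em.feature_names.index(f) for f in em.spec.selected_features]
                x = x[:, idx]
            if em.spec.task == "classification":
                prob = float(_positive_scores(em.estimator, x)[0])
                row[f"{name}_prob"] = prob
                row[f"{name}_class"] = int(prob >= threshold)
            else:
                row[f"{name}_value"] = float(em.estimator.predict(x)[0])
        rows.append(row)
    frame = pd.DataFrame(
        {"id": [r.id for r in records], "smiles": [r.smiles for r in records]}
    )
    preds = pd.DataFrame(rows) if any(rows) else pd.DataFrame(index=range(len(rows)))
    frame = pd.concat([frame, preds], axis=1)
    return frame, rows


def training_checksum(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(_as_matrix(X)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y)).tobytes())
    return h.hexdigest()


def save_model(path, estimator, spec: ModelSpec, checksum: str = "", extra: dict = None):
    """Persist an estimator with an adjacent plain-text spec file."""
    path = Path(path)
    joblib.dump(estimator, path)
    meta = {"format_version": 1, **asdict(spec), "training_checksum": checksum}
    meta.update(extra or {})
    path.with_suffix(path.suffix + ".spec.json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


def load_model(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".spec.json").read_text())
    spec = ModelSpec(
        task=meta["task"],
        algorithm=meta["algorithm"],
        hyperparameters=meta["hyperparameters"],
        seed=meta["seed"],
        selected_features=meta.get("selected_features"),
    )
    return joblib.load(path), spec, meta
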