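"""Classifier training, nested cross-validation and comparison.

Five classifier families operate on the four-feature table (SDNR, RMSE,
FWHM, PSR) with the review labels as targets.  Model selection is a nested
scheme: an outer stratified 10-fold CV estimates generalisation metrics,
and inside each outer training split a 5-fold grid search picks
hyperparameters by AUC.  The deliverable model is refitted on all data with
the modal fold-winning hyperparameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InsufficientDataError, SchemaMismatchError, UnknownFamilyError
from .metrics import ConfusionTable, MetricSet, binary_metrics, roc_auc

FEATURE_NAMES = ["sdnr", "rmse_norm", "fwhm_s", "psr_pct"]
LABEL_COLUMN = "qr_label"

FAMILIES = ("binary_tree", "svm", "ensemble_bag", "random_forest", "logistic_regression")

SCHEMA_VERSION = 1


def _default_grid(family: str) -> Dict[str, list]:
    if family == "binary_tree":
        return {"max_depth": [2, 4, 8, None], "min_samples_leaf": [1, 5, 20]}
    if family == "svm":
        return {"clf__kernel": ["linear", "rbf"], "clf__C": [0.1, 1.0, 10.0]}
    if family == "ensemble_bag":
        return {"n_estimators": [100, 300], "estimator__min_samples_leaf": [1, 5, 20]}
    if family == "random_forest":
        return {"n_estimators": [100, 300], "min_samples_leaf": [1, 5, 20]}
    if family == "logistic_regression":
        # grid over inverse L2 strength
        return {"clf__C": [0.1, 1.0, 10.0, 100.0]}
    raise UnknownFamilyError(f"unknown family {family!r}")


@dataclass
class ClassifierSpec:
    """One classifier family plus its hyperparameter search space."""

    family: str
    grid: Dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UnknownFamilyError(f"unknown family {self.family!r}")
        if not self.grid:
            self.grid = _default_grid(self.family)


def _base_estimator(family: str, seed: int):
    if family == "binary_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "svm":
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(random_state=seed))])
    if family == "ensemble_bag":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "logistic_regression":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
        ])
    raise UnknownFamilyError(f"unknown family {family!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous [0,1] quality score: class-1 probability when available,
    otherwise decision-function distance through a logistic link."""
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
            cls = list(model.classes_)
            return proba[:, cls.index(1)]
        except AttributeError:
            pass
    z = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class CvReport:
    """Outer-CV performance summary for one classifier family."""

    family: str
    per_fold: List[MetricSet]
    mean: MetricSet
    chosen_params: List[Dict]
    k: int


@dataclass
class FittedModel:
    """Deliverable model plus the metadata needed to audit predictions."""

    model: object
    family: str
    feature_names: List[str]
    hyperparameters: Dict
    fingerprint: str
    schema_version: int = SCHEMA_VERSION

    def save(self, path) -> None:
        joblib.dump({
            "schema_version": self.schema_version,
            "family": self.family,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "fingerprint": self.fingerprint,
            "model": self.model,
        }, path)

    @classmethod
    def load(cls, path) -> "FittedModel":
        d = joblib.load(path)
        return cls(
            model=d["model"],
            family=d["family"],
            feature_names=list(d["feature_names"]),
            hyperparameters=dict(d["hyperparameters"]),
            fingerprint=d["fingerprint"],
            schema_version=int(d["schema_version"]),
        )


def _validate_table(table: pd.DataFrame, k: int) -> Tuple[np.ndarray, np.ndarray]:
    missing = set(FEATURE_NAMES + [LABEL_COLUMN]) - set(table.columns)
    if missing:
        raise SchemaMismatchError(f"table missing columns: {sorted(missing)}")
    X = table[FEATURE_NAMES].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts[0] < k or counts[1] < k:
        raise InsufficientDataError(
            f"insufficient data: class counts {counts.tolist()} for k={k}"
        )
    return X, y


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_classifier(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
) -> Tuple[FittedModel, CvReport]:
    """Nested-CV training for one family.

    Hyperparameters are searched on each outer training split only (inner
    stratified 5-fold, AUC scoring); outer test folds are touched once, for
    metric computation.  The final model is refitted on all rows with the
    modal per-fold winning hyperparameters.
    """
    X, y = _validate_table(table, k)

    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + 1)

    per_fold: List[MetricSet] = []
    chosen: List[Dict] = []
    for train_idx, test_idx in outer.split(X, y):
        search = GridSearchCV(
            _base_estimator(spec.family, spec.seed),
            spec.grid,
            scoring="roc_auc",
            cv=inner,
            refit=True,
            n_jobs=1,
        )
        search.fit(X[train_idx], y[train_idx])
        chosen.append(dict(search.best_params_))
        best = search.best_estimator_
        pred = best.predict(X[test_idx])
        ms = binary_metrics(ConfusionTable.from_predictions(y[test_idx], pred))
        ms.auc = roc_auc(_scores(best, X[test_idx]), y[test_idx])
        per_fold.append(ms)

    def _mean(vals: Sequence[Optional[float]]) -> Optional[float]:
        present = [v for v in vals if v is not None]
        return float(np.mean(present)) if present else None

    mean = MetricSet(
        sensitivity=_mean([m.sensitivity for m in per_fold]),
        specificity=_mean([m.specificity for m in per_fold]),
        precision=_mean([m.precision for m in per_fold]),
        classification_error=_mean([m.classification_error for m in per_fold]),
        auc=_mean([m.auc for m in per_fold]),
    )
    report = CvReport(family=spec.family, per_fold=per_fold, mean=mean,
                      chosen_params=chosen, k=k)

    # modal hyperparameters; ties broken by canonical JSON ordering
    keys = [json.dumps(p, sort_keys=True) for p in chosen]
    uniq, counts = np.unique(keys, return_counts=True)
    modal = json.loads(sorted(zip(-counts, uniq))[0][1])

    final = clone(_base_estimator(spec.family, spec.seed))
    final.set_params(**modal)
    final.fit(X, y)
    fitted = FittedModel(
        model=final,
        family=spec.family,
        feature_names=list(FEATURE_NAMES),
        hyperparameters=modal,
        fingerprint=_fingerprint(X, y),
    )
    return fitted, report


def predict_quality(model: FittedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-row pass/fail labels and [0,1] scores.

    Rows flagged invalid (``valid`` column false, or non-finite feature
    values) fail with their reason rather than being dropped.
    """
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise SchemaMismatchError(f"model/feature schema mismatch: missing {sorted(missing)}")
    X = features[model.feature_names].to_numpy(dtype=float)
    finite = np.all(np.isfinite(X), axis=1)
    if "valid" in features.columns:
        finite &= features["valid"].to_numpy().astype(bool)

    labels = np.zeros(len(features), dtype=int)
    scores = np.full(len(features), np.nan)
    reasons = np.array([""] * len(features), dtype=object)
    if finite.any():
        labels[finite] = model.model.predict(X[finite])
        scores[finite] = _scores(model.model, X[finite])
    if (~finite).any():
        if "reason" in features.columns:
            src = features["reason"].to_numpy(dtype=object)
            reasons[~finite] = [str(r) if str(r) else "invalid features" for r in src[~finite]]
        else:
            reasons[~finite] = "invalid features"
    return pd.DataFrame({
        "label": labels,
        "score": scores,
        "reason": reasons,
    }, index=features.index)


def compare_classifiers(
    table: pd.DataFrame,
    specs: Sequence[ClassifierSpec],
    k: int = 10,
    seed: int = 0,
) -> Tuple[pd.DataFrame, str, Dict[str, FittedModel]]:
    """Train every family and tabulate mean outer-CV metrics.

    Returns the comparison table (one row per family), the winning family
    (lowest classification error; ties by higher AUC, then alphabetical),
    and the fitted deliverable models.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 classifier specs to compare")
    rows = []
    models: Dict[str, FittedModel] = {}
    for spec in specs:
        fitted, report = train_classifier(table, spec, k=k, seed=seed)
        models[spec.family] = fitted
        rows.append({
            "family": spec.family,
            "sensitivity": report.mean.sensitivity,
            "specificity": report.mean.specificity,
            "precision": report.mean.precision,
            "classification_error": report.mean.classification_error,
            "auc": report.mean.auc,
        })
    df = pd.DataFrame(rows)
    ranked = df.sort_values(
        by=["classification_error", "auc", "family"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return df, str(ranked.iloc[0]["family"]), models
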