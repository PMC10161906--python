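"""Rater-label-driven threshold calibration via stratified k-fold CV.

SDNR and RMSE get single cut-offs placed where training sensitivity equals
specificity; FWHM and PSR get inclusive acceptance ranges spanning the
smallest and largest training values that passed review.  Headline
thresholds are fold means; per-fold values are kept for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import (
    InsufficientDataError,
    NoPassingExamplesError,
    SingleClassError,
)
from .metrics import ConfusionTable, MetricSet, binary_metrics, roc_auc

#: Measures with a single cut-off and their orientation.
CUTOFF_MEASURES = {"sdnr": "higher_is_better", "rmse_norm": "lower_is_better"}
#: Measures with an inclusive acceptance range.
RANGE_MEASURES = ("fwhm_s", "psr_pct")

LABEL_COLUMN = "qr_label"


@dataclass
class ThresholdSet:
    """Calibrated cut-offs and acceptance ranges with per-fold provenance."""

    sdnr_min: float
    rmse_max: float
    fwhm_range: Tuple[float, float]
    psr_range: Tuple[float, float]
    per_fold: List[Dict] = field(default_factory=list)
    k: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_range[0] > self.fwhm_range[1]:
            raise ValueError("fwhm_range low > high")
        if self.psr_range[0] > self.psr_range[1]:
            raise ValueError("psr_range low > high")
        if self.per_fold and len(self.per_fold) != self.k:
            raise ValueError("per_fold length must equal k")

    def to_dict(self) -> Dict:
        return {
            "sdnr_min": float(self.sdnr_min),
            "rmse_max": float(self.rmse_max),
            "fwhm_range": [float(v) for v in self.fwhm_range],
            "psr_range": [float(v) for v in self.psr_range],
            "k": self.k,
            "per_fold": self.per_fold,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Dict) -> "ThresholdSet":
        return cls(
            sdnr_min=float(d["sdnr_min"]),
            rmse_max=float(d["rmse_max"]),
            fwhm_range=tuple(d["fwhm_range"]),
            psr_range=tuple(d["psr_range"]),
            per_fold=list(d.get("per_fold", [])),
            k=int(d.get("k", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def crossing_threshold(
    values: Sequence[float],
    labels: Sequence[int],
    orientation: str,
) -> float:
    """Cut-off where training sensitivity equals specificity.

    Candidates are the observed unique values.  A sample passes when
    ``value >= theta`` (``higher_is_better``) or ``value <= theta``
    (``lower_is_better``).  Returns the candidate minimising
    ``|sensitivity - specificity|``; ties broken by larger
    ``sensitivity + specificity``, then by smaller theta.
    """
    if orientation not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("single-class input")

    pos = y == 1
    best = None  # (absdiff, -sum, theta)
    for theta in np.unique(v):
        pred = v >= theta if orientation == "higher_is_better" else v <= theta
        sens = float(np.mean(pred[pos]))
        spec = float(np.mean(~pred[~pos]))
        key = (abs(sens - spec), -(sens + spec), theta)
        if best is None or key < best:
            best = key
    return float(best[2])


def range_thresholds(
    values: Sequence[float],
    labels: Sequence[int],
) -> Tuple[float, float]:
    """(min, max) of the values that passed review; applied inclusively."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    passing = v[y == 1]
    if passing.size == 0:
        raise NoPassingExamplesError("no passing examples")
    return float(passing.min()), float(passing.max())


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> List[np.ndarray]:
    """Label-stratified fold assignment.

    Indices are shuffled within each class with the given seed and dealt
    round-robin into k folds, keeping per-fold class proportions within one
    record of the global proportions.
    """
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    folds: List[List[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise InsufficientDataError(
                f"insufficient class counts for {k} folds (class {cls}: {idx.size})"
            )
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _predict_cutoff(values: np.ndarray, theta: float, orientation: str) -> np.ndarray:
    return values >= theta if orientation == "higher_is_better" else values <= theta


def _predict_range(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (values >= lo) & (values <= hi)


def _range_scores(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # AUC for a two-sided rule: sweep one symmetric inflation factor about
    # the range midpoint, i.e. score by negative scaled distance from centre.
    mid = 0.5 * (lo + hi)
    half = max(0.5 * (hi - lo), 1e-12)
    return -np.abs(values - mid) / half


def calibrate_kfold(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> Tuple[ThresholdSet, Dict[str, MetricSet]]:
    """Calibrate all four measures with stratified k-fold CV.

    ``table`` needs columns ``sdnr``, ``rmse_norm``, ``fwhm_s``, ``psr_pct``
    and the binary ``qr_label``.  Per fold, thresholds are fitted on the
    k-1 training folds and metrics evaluated on the held-out fold; headline
    thresholds and metrics are arithmetic fold means.

    Returns the ThresholdSet and a dict of mean test metrics per measure.
    """
    required = set(CUTOFF_MEASURES) | set(RANGE_MEASURES) | {LABEL_COLUMN}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    y = table[LABEL_COLUMN].to_numpy().astype(int)
    folds = stratified_folds(y, k, seed)

    per_fold: List[Dict] = []
    fold_metrics: Dict[str, List[MetricSet]] = {
        m: [] for m in (*CUTOFF_MEASURES, *RANGE_MEASURES)
    }

    all_idx = np.arange(len(table))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr, y_te = y[train_idx], y[test_idx]
        entry: Dict = {"fold": f}

        for meas, orient in CUTOFF_MEASURES.items():
            v_tr = table[meas].to_numpy()[train_idx]
            v_te = table[meas].to_numpy()[test_idx]
            theta = crossing_threshold(v_tr, y_tr, orient)
            entry[meas] = theta
            pred = _predict_cutoff(v_te, theta, orient)
            ms = binary_metrics(ConfusionTable.from_predictions(y_te, pred))
            scores = v_te if orient == "higher_is_better" else -v_te
            ms.auc = roc_auc(scores, y_te)
            fold_metrics[meas].append(ms)

        for meas in RANGE_MEASURES:
            v_tr = table[meas].to_numpy()[train_idx]
            v_te = table[meas].to_numpy()[test_idx]
            lo, hi = range_thresholds(v_tr, y_tr)
            entry[meas] = (lo, hi)
            pred = _predict_range(v_te, lo, hi)
            ms = binary_metrics(ConfusionTable.from_predictions(y_te, pred))
            ms.auc = roc_auc(_range_scores(v_te, lo, hi), y_te)
            fold_metrics[meas].append(ms)

        per_fold.append(entry)

    def _mean(vals: List[Optional[float]]) -> Optional[float]:
        present = [v for v in vals if v is not None]
        return float(np.mean(present)) if present else None

    mean_metrics = {
        meas: MetricSet(
            sensitivity=_mean([m.sensitivity for m in ml]),
            specificity=_mean([m.specificity for m in ml]),
            precision=_mean([m.precision for m in ml]),
            classification_error=_mean([m.classification_error for m in ml]),
            auc=_mean([m.auc for m in ml]),
        )
        for meas, ml in fold_metrics.items()
    }

    ts = ThresholdSet(
        sdnr_min=float(np.mean([e["sdnr"] for e in per_fold])),
        rmse_max=float(np.mean([e["rmse_norm"] for e in per_fold])),
        fwhm_range=(
            float(np.mean([e["fwhm_s"][0] for e in per_fold])),
            float(np.mean([e["fwhm_s"][1] for e in per_fold])),
        ),
        psr_range=(
            float(np.mean([e["psr_pct"][0] for e in per_fold])),
            float(np.mean([e["psr_pct"][1] for e in per_fold])),
        ),
        per_fold=per_fold,
        k=k,
    )
    return ts, mean_metrics


def apply_thresholds(features, thresholds: ThresholdSet, measure: str):
    """Predict pass/fail for one feature row under one threshold rule.

    ``features`` may be a QualityFeatures object, a mapping, or a pandas
    row with the feature-table column names.  ``measure`` is one of
    ``sdnr``, ``rmse_norm``, ``fwhm_s``, ``psr_pct`` or ``all`` (every rule
    must pass).  Invalid features fail with their reason; no exceptions.

    Returns ``(label, reason)`` with label in {0, 1}.
    """
    from .features import QualityFeatures  # local import avoids a cycle

    if isinstance(features, QualityFeatures):
        row = {
            "sdnr": features.sdnr,
            "rmse_norm": features.rmse_norm,
            "fwhm_s": features.fwhm_seconds,
            "psr_pct": features.psr_percent,
        }
        flags = features.flags
        reason = features.reason
    else:
        row = features
        flags = {m: np.isfinite(row.get(m, np.nan)) for m in (*CUTOFF_MEASURES, *RANGE_MEASURES)}
        reason = str(row.get("reason", "")) if hasattr(row, "get") else ""

    measures = list((*CUTOFF_MEASURES, *RANGE_MEASURES)) if measure == "all" else [measure]
    for m in measures:
        if m not in (*CUTOFF_MEASURES, *RANGE_MEASURES):
            raise ValueError(f"unknown measure {m!r}")
        if not flags.get(m, False):
            return 0, reason or f"{m} invalid"
        v = float(row[m])
        if m == "sdnr" and not v >= thresholds.sdnr_min:
            return 0, f"sdnr {v:.3g} < {thresholds.sdnr_min:.3g}"
        if m == "rmse_norm" and not v <= thresholds.rmse_max:
            return 0, f"rmse_norm {v:.3g} > {thresholds.rmse_max:.3g}"
        if m == "fwhm_s" and not (thresholds.fwhm_range[0] <= v <= thresholds.fwhm_range[1]):
            return 0, f"fwhm_s {v:.3g} outside {thresholds.fwhm_range}"
        if m == "psr_pct" and not (thresholds.psr_range[0] <= v <= thresholds.psr_range[1]):
            return 0, f"psr_pct {v:.3g} outside {thresholds.psr_range}"
    return 1, ""
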