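"""Binary classification metrics and interrater agreement statistics.

The accepted label (1) is the positive class throughout.  Human-readable
reports round to 2 decimals; everything here returns full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import LengthMismatchError, SingleClassError


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts with accepted (label 1) as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionTable":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise LengthMismatchError("length mismatch")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )


@dataclass
class MetricSet:
    """Performance metrics for one evaluation.

    Metrics with a zero denominator are ``None`` and listed in
    ``undefined`` rather than raising.
    """

    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    precision: Optional[float] = None
    classification_error: Optional[float] = None  # percent
    auc: Optional[float] = None
    undefined: tuple = ()

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "classification_error": self.classification_error,
            "auc": self.auc,
        }


def binary_metrics(ct: ConfusionTable) -> MetricSet:
    """Sensitivity, specificity, precision and classification error (%)."""
    undefined = []

    def _ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = _ratio(ct.tp, ct.tp + ct.fn, "sensitivity")
    spec = _ratio(ct.tn, ct.tn + ct.fp, "specificity")
    prec = _ratio(ct.tp, ct.tp + ct.fp, "precision")
    err = 100.0 * (ct.fp + ct.fn) / ct.total
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        classification_error=err,
        undefined=tuple(undefined),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie).
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("single-class input")
    return float(roc_auc_score(labels, scores))


def percent_disagreement(r1: Sequence[int], r2: Sequence[int]) -> float:
    """Percentage of positions where two binary rating vectors differ."""
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape:
        raise LengthMismatchError("length mismatch")
    if a.size == 0:
        raise ValueError("empty rating vectors")
    return 100.0 * float(np.mean(a != b))


def cohens_kappa(r1: Sequence[int], r2: Sequence[int]) -> float:
    """Cohen's kappa for two raters over the same items.

    kappa = (p_o - p_e) / (1 - p_e) where p_o is observed agreement and
    p_e the chance agreement from the raters' marginals.  Returns exactly
    1.0 when the raters agree everywhere (including the degenerate case
    p_e = 1, by convention).
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape:
        raise LengthMismatchError("length mismatch")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    p_o = float(np.mean(a == b))
    if p_o == 1.0:
        return 1.0
    cats = np.union1d(a, b)
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementReport:
    n_pairs: int
    percent_disagreement: float
    kappa: float


def agreement_report(
    r1: Sequence[int],
    r2: Sequence[int],
    groups: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Overall (and optionally per-subgroup) disagreement and kappa.

    ``groups``, when given, assigns each rating pair to a subgroup (e.g.
    field strength); one row per subgroup is appended after the overall row.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape:
        raise LengthMismatchError("length mismatch")
    rows = [{
        "group": "all",
        "n_pairs": int(a.size),
        "percent_disagreement": percent_disagreement(a, b),
        "kappa": cohens_kappa(a, b),
    }]
    if groups is not None:
        g = np.asarray(groups)
        if g.shape != a.shape:
            raise LengthMismatchError("length mismatch")
        for name in pd.unique(g):
            m = g == name
            rows.append({
                "group": str(name),
                "n_pairs": int(m.sum()),
                "percent_disagreement": percent_disagreement(a[m], b[m]),
                "kappa": cohens_kappa(a[m], b[m]),
            })
    return pd.DataFrame(rows)
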