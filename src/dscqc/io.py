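"""Volume I/O and voxel-wise quality maps.

Loads 4D NIfTI volumes into per-voxel signal-time courses, runs a chosen
QC method (calibrated thresholds or a trained classifier) over every
in-mask voxel, and writes 3D quality maps (1 pass, 0 fail, NaN excluded)
with JSON provenance sidecars.

Spatial indices are 0-based (array order of the volume); dynamic indices
inside reports are 1-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .calibration import ThresholdSet, apply_thresholds
from .errors import Not4DError, TrUnavailableError
from .features import QualityFeatures, extract_features, features_to_frame
from .ml import FittedModel, predict_quality
from .signal_model import SignalTimeCourse

logger = logging.getLogger("dscqc")

#: Default mask: voxels whose temporal mean exceeds this fraction of the
#: robust (98th percentile) maximum of the mean image.
DEFAULT_MASK_FRACTION = 0.05


@dataclass
class DscVolume:
    """A loaded 4D acquisition flattened to in-mask signal-time courses."""

    courses: List[SignalTimeCourse]
    shape: Tuple[int, int, int]
    affine: np.ndarray
    tr_seconds: float
    mask: np.ndarray


def _default_mask(data: np.ndarray) -> np.ndarray:
    mean_img = data.mean(axis=3)
    robust_max = np.percentile(mean_img, 98)
    return mean_img > DEFAULT_MASK_FRACTION * robust_max


def load_dsc_volume(
    path,
    tr_override: Optional[float] = None,
    mask_path=None,
) -> DscVolume:
    """Load a 4D NIfTI into one SignalTimeCourse per in-mask voxel.

    TR priority: explicit override > header 4th zoom.  A mismatch between
    the two above 1 ms logs a warning.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise Not4DError(f"not 4D: {path} has {img.ndim} dimensions")
    data = np.asarray(img.get_fdata(), dtype=float)

    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_override is not None:
        tr = float(tr_override)
        if header_tr > 0 and abs(header_tr - tr) > 1e-3:
            logger.warning(
                "TR override %.4fs differs from header %.4fs", tr, header_tr
            )
    elif header_tr > 0:
        tr = header_tr
    else:
        raise TrUnavailableError("TR unavailable: not in header and no override given")

    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match volume")
    else:
        mask = _default_mask(data)

    courses = [
        SignalTimeCourse(data[i, j, k, :], tr, voxel_id=(int(i), int(j), int(k)))
        for i, j, k in zip(*np.nonzero(mask))
    ]
    return DscVolume(
        courses=courses, shape=data.shape[:3], affine=img.affine,
        tr_seconds=tr, mask=mask,
    )


@dataclass
class QualityMap:
    """3D pass/fail grid (1/0, NaN excluded) plus provenance."""

    labels: np.ndarray
    provenance: Dict
    pass_rate: Optional[float]  # % passed among valid voxels
    n_valid: int

    def summary(self) -> Dict:
        return {
            "n_valid": self.n_valid,
            "percent_passed": self.pass_rate,
            **self.provenance,
        }


def make_quality_map(
    volume: DscVolume,
    method: str,
    thresholds: Optional[ThresholdSet] = None,
    measures: Tuple[str, ...] = ("sdnr",),
    model: Optional[FittedModel] = None,
    min_baseline: int = 5,
    k_sigma: float = 2.5,
) -> Tuple[QualityMap, pd.DataFrame]:
    """Per-voxel QC over an entire volume.

    ``method`` is ``"threshold"`` (apply ``thresholds`` on each measure in
    ``measures``; all must pass) or ``"model"`` (a FittedModel).  Returns
    the map and the underlying feature table.  The pass-rate summary counts
    valid voxels only and flags an empty denominator with ``None``.
    """
    feats: List[QualityFeatures] = [
        extract_features(c, min_baseline=min_baseline, k_sigma=k_sigma)
        for c in volume.courses
    ]
    table = features_to_frame(feats)
    labels = np.full(volume.shape, np.nan)

    if method == "threshold":
        if thresholds is None:
            raise ValueError("threshold method needs a ThresholdSet")
        provenance = {
            "method": "threshold",
            "measures": list(measures),
            "thresholds": {k: v for k, v in thresholds.to_dict().items() if k != "per_fold"},
        }
        preds = []
        for f in feats:
            label = 1
            for m in measures:
                li, _ = apply_thresholds(f, thresholds, m)
                label &= li
            ok = all(f.flags.get(m, False) for m in measures) and f.flags
            preds.append((label, ok))
    elif method == "model":
        if model is None:
            raise ValueError("model method needs a FittedModel")
        provenance = {
            "method": "model",
            "family": model.family,
            "hyperparameters": model.hyperparameters,
            "fingerprint": model.fingerprint,
        }
        out = predict_quality(model, table)
        preds = [
            (int(l), bool(v))
            for l, v in zip(out["label"], table["valid"])
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    n_valid = 0
    n_pass = 0
    for f, (label, ok) in zip(feats, preds):
        i, j, k = f.voxel_id
        if not ok:
            continue
        n_valid += 1
        n_pass += int(label)
        labels[i, j, k] = float(label)

    pass_rate = 100.0 * n_pass / n_valid if n_valid > 0 else None
    if pass_rate is None:
        logger.warning("quality map has no valid voxels (empty denominator)")
    return QualityMap(labels=labels, provenance=provenance,
                      pass_rate=pass_rate, n_valid=n_valid), table


def write_quality_map(qmap: QualityMap, path, affine: Optional[np.ndarray] = None) -> None:
    """NIfTI map plus a ``.json`` provenance sidecar."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(qmap.labels.astype(np.float64), affine), str(path))
    sidecar = str(path).removesuffix(".gz").removesuffix(".nii") + ".json"
    with open(sidecar, "w") as fh:
        json.dump(qmap.summary(), fh, indent=2, default=str)


def load_quality_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())
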