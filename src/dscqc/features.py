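"""Quantitative quality measures of a segmented signal-time course.

Four measures are computed per voxel:

* **SDNR** — signal drop divided by the baseline standard deviation, where
  the signal drop is the mean baseline minus the mean of the first-pass
  minimum and its two adjacent dynamics.
* **RMSE** — root mean square error of a simplified gamma-variate fit
  ``y(t) = c - K * t**alpha * exp(-t / beta)`` to the first pass, with the
  baseline level ``c`` fixed at the baseline mean; normalised by the
  trapezoidal area of the drop curve over the first pass (units 1/s).
* **FWHM** — temporal width of the first pass at half the signal drop,
  linearly interpolated, in seconds.
* **PSR** — percentage signal recovery: post-bolus recovery relative to the
  signal drop, times 100.

``extract_features`` orchestrates segmentation plus all four measures and
degrades per-measure failures to validity flags so a feature table can
always be assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DegenerateBaselineError,
    DscQcError,
    FirstPassTooShortError,
    MinimumAtBoundaryError,
    NoHalfLevelCrossingError,
    ZeroSignalDropError,
)
from .signal_model import (
    DEFAULT_K_SIGMA,
    DEFAULT_MIN_BASELINE,
    FirstPassSegmentation,
    SignalTimeCourse,
    segment_first_pass,
)

#: rmse_norm reported for non-convergent gamma-variate fits.
RMSE_SENTINEL = 1.0

GAMMA_BOUNDS = ((0.0, 1e-9, 0.1), (np.inf, 10.0, 100.0))  # (K, alpha, beta)

MEASURES = ("sdnr", "rmse_norm", "fwhm_s", "psr_pct")

FEATURE_COLUMNS = [
    "voxel_id", "i", "j", "k", "baseline_end", "postbolus_start",
    "sdnr", "rmse_norm", "fwhm_s", "psr_pct", "valid", "reason",
]


@dataclass
class GammaFit:
    """Result of the gamma-variate first-pass fit."""

    c: float
    K: float
    alpha: float
    beta: float
    rmse_norm: float
    converged: bool


@dataclass
class QualityFeatures:
    """The four quality measures plus per-measure validity flags."""

    signal_drop: float = np.nan
    baseline_sd: float = np.nan
    sdnr: float = np.nan
    rmse_norm: float = np.nan
    fwhm_seconds: float = np.nan
    psr_percent: float = np.nan
    baseline_end: Optional[int] = None
    postbolus_start: Optional[int] = None
    flags: Dict[str, bool] = field(default_factory=dict)
    reason: str = ""
    voxel_id: object = None

    @property
    def valid(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


def _baseline_mean(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    return float(signal.values[seg.baseline_slice].mean())


def _min_index0(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> int:
    """0-based index of the first-pass minimum in the full series.

    Ties broken by earliest index (argmin convention).
    """
    fp = signal.values[seg.first_pass_slice]
    return seg.first_pass_slice.start + int(np.argmin(fp))


def _min3_mean(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    """Mean of the first-pass minimum and its two adjacent dynamics.

    Neighbours come from the full series even if they fall outside the
    first pass.
    """
    m0 = _min_index0(signal, seg)
    if m0 == 0 or m0 == signal.n - 1:
        raise MinimumAtBoundaryError("minimum at series boundary")
    return float(signal.values[m0 - 1 : m0 + 2].mean())


def signal_drop(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    """Mean baseline minus mean of the first-pass minimum and neighbours."""
    return _baseline_mean(signal, seg) - _min3_mean(signal, seg)


def sdnr(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    """Signal drop-to-noise ratio: drop / sample SD of the baseline."""
    sd = float(signal.values[seg.baseline_slice].std(ddof=1))
    if sd == 0:
        raise DegenerateBaselineError("degenerate baseline")
    return signal_drop(signal, seg) / sd


def _gamma_model(t: np.ndarray, K: float, alpha: float, beta: float, c: float) -> np.ndarray:
    return c - K * np.power(t, alpha) * np.exp(-t / beta)


def fit_gamma_variate(
    signal: SignalTimeCourse,
    seg: FirstPassSegmentation,
    normalisation: str = "drop_area",
) -> GammaFit:
    """Nonlinear least-squares gamma-variate fit over the first pass.

    Time is measured from the baseline end: ``t = (index - b) * TR`` so the
    first first-pass dynamic sits at ``t = TR``.  ``c`` is fixed at the
    baseline mean; only ``K``, ``alpha``, ``beta`` are free.

    ``normalisation`` selects the area used to normalise the RMSE:
    ``"drop_area"`` (default) integrates ``baseline mean - signal``;
    ``"signal_area"`` integrates the raw signal.  Non-convergence is not an
    error: the fit is flagged and ``rmse_norm`` set to the sentinel 1.0.
    """
    b = seg.baseline_end
    idx1 = np.arange(b + 1, seg.postbolus_start)  # 1-based first-pass dynamics
    if idx1.size < 4:
        raise FirstPassTooShortError("first pass too short")
    t = (idx1 - b) * signal.tr_seconds
    y = signal.values[seg.first_pass_slice]
    c = _baseline_mean(signal, seg)

    duration = t[-1]
    alpha0 = 1.5
    beta0 = float(np.clip(duration / 4.0, GAMMA_BOUNDS[0][2], GAMMA_BOUNDS[1][2]))
    peak_drop = max(float(np.max(c - y)), 1e-12)
    t_pk = alpha0 * beta0
    g_pk = t_pk**alpha0 * np.exp(-t_pk / beta0)
    K0 = peak_drop / g_pk if g_pk > 0 else 1.0

    if normalisation == "drop_area":
        area = float(np.trapezoid(c - y, t))
    elif normalisation == "signal_area":
        area = float(np.trapezoid(y, t))
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")

    try:
        popt, _ = curve_fit(
            lambda tt, K, a, bb: _gamma_model(tt, K, a, bb, c),
            t,
            y,
            p0=(K0, alpha0, beta0),
            bounds=GAMMA_BOUNDS,
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return GammaFit(c=c, K=np.nan, alpha=np.nan, beta=np.nan,
                        rmse_norm=RMSE_SENTINEL, converged=False)

    K, alpha, beta = (float(v) for v in popt)
    resid = y - _gamma_model(t, K, alpha, beta, c)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if area <= 0 or not np.isfinite(area):
        return GammaFit(c=c, K=K, alpha=alpha, beta=beta,
                        rmse_norm=RMSE_SENTINEL, converged=False)
    return GammaFit(c=c, K=K, alpha=alpha, beta=beta,
                    rmse_norm=rmse / area, converged=True)


def fwhm(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    """Width of the first pass at half the signal drop, in seconds.

    The half level is ``baseline mean - drop/2`` with the drop from the
    3-point minimum mean.  From the minimum, the nearest bracketing
    adjacent-dynamic pair on each side is linearly interpolated.
    """
    drop = signal_drop(signal, seg)
    if drop <= 0:
        raise ZeroSignalDropError("zero signal drop")
    base = _baseline_mean(signal, seg)
    half = base - drop / 2.0
    v = signal.values
    m0 = _min_index0(signal, seg)

    x_left = None
    for j in range(m0, 0, -1):
        if v[j] < half <= v[j - 1]:
            x_left = (j - 1) + (v[j - 1] - half) / (v[j - 1] - v[j])
            break
    x_right = None
    for j in range(m0, signal.n - 1):
        if v[j] < half <= v[j + 1]:
            x_right = j + (half - v[j]) / (v[j + 1] - v[j])
            break
    if x_left is None or x_right is None:
        raise NoHalfLevelCrossingError("no half-level crossing")
    return float((x_right - x_left) * signal.tr_seconds)


def psr(signal: SignalTimeCourse, seg: FirstPassSegmentation) -> float:
    """Percentage signal recovery.

    100 * (mean post-bolus signal - 3-point minimum mean) / signal drop.
    """
    drop = signal_drop(signal, seg)
    if drop <= 0:
        raise ZeroSignalDropError("zero signal drop")
    post = float(signal.values[seg.postbolus_slice].mean())
    return 100.0 * (post - _min3_mean(signal, seg)) / drop


def extract_features(
    signal: SignalTimeCourse,
    min_baseline: int = DEFAULT_MIN_BASELINE,
    k_sigma: float = DEFAULT_K_SIGMA,
    normalisation: str = "drop_area",
) -> QualityFeatures:
    """Segment the course and compute all four measures.

    Per-measure errors become validity flags, never exceptions; only a
    segmentation failure marks the whole voxel invalid.
    """
    out = QualityFeatures(voxel_id=signal.voxel_id)
    try:
        seg = segment_first_pass(signal, min_baseline, k_sigma)
    except DscQcError as exc:
        out.flags = {m: False for m in MEASURES}
        out.reason = str(exc)
        return out

    out.baseline_end = seg.baseline_end
    out.postbolus_start = seg.postbolus_start
    reasons: List[str] = []

    try:
        out.signal_drop = signal_drop(signal, seg)
    except DscQcError as exc:
        reasons.append(str(exc))

    try:
        out.baseline_sd = float(signal.values[seg.baseline_slice].std(ddof=1))
        out.sdnr = sdnr(signal, seg)
        out.flags["sdnr"] = True
    except DscQcError as exc:
        out.flags["sdnr"] = False
        reasons.append(str(exc))

    try:
        fit = fit_gamma_variate(signal, seg, normalisation=normalisation)
        out.rmse_norm = fit.rmse_norm
        out.flags["rmse_norm"] = True  # non-convergence carries the sentinel
    except DscQcError as exc:
        out.flags["rmse_norm"] = False
        reasons.append(str(exc))

    try:
        out.fwhm_seconds = fwhm(signal, seg)
        out.flags["fwhm_s"] = True
    except DscQcError as exc:
        out.flags["fwhm_s"] = False
        reasons.append(str(exc))

    try:
        out.psr_percent = psr(signal, seg)
        out.flags["psr_pct"] = True
    except DscQcError as exc:
        out.flags["psr_pct"] = False
        reasons.append(str(exc))

    out.reason = "; ".join(dict.fromkeys(reasons))
    return out


def features_to_frame(rows: Sequence[QualityFeatures]) -> pd.DataFrame:
    """Assemble extracted features into the canonical CSV-ready table."""
    records = []
    for r in rows:
        i = j = k = None
        vid = r.voxel_id
        if isinstance(vid, tuple) and len(vid) == 3:
            i, j, k = (int(x) for x in vid)
        records.append({
            "voxel_id": str(vid) if vid is not None else "",
            "i": i, "j": j, "k": k,
            "baseline_end": r.baseline_end,
            "postbolus_start": r.postbolus_start,
            "sdnr": r.sdnr,
            "rmse_norm": r.rmse_norm,
            "fwhm_s": r.fwhm_seconds,
            "psr_pct": r.psr_percent,
            "valid": r.valid,
            "reason": r.reason,
        })
    return pd.DataFrame.from_records(records, columns=FEATURE_COLUMNS)
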