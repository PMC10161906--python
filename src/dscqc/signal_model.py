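"""Signal-time course types and first-pass segmentation.

A dynamic susceptibility contrast acquisition yields, per voxel, a sequence
of signal intensities ("dynamics") spaced by the repetition time TR.  The
bolus first pass is the transient dip between a pre-bolus baseline plateau
and a post-bolus plateau.  Both plateau boundaries are found by comparing a
trailing 3-point moving mean against the cumulative mean from the series
start: the first dynamic where the two diverge beyond the baseline noise
marks the end of the plateau.  The post-bolus boundary uses the identical
rule on the time-reversed series.

All indices reported by this module are 1-based and inclusive, matching how
dynamics are counted in scanner protocols.  Internally numpy arrays are
0-based; the translation happens at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    DegenerateFirstPassError,
    NoBolusError,
    SeriesTooShortError,
)

#: Default minimum number of baseline dynamics.  Shorter baselines give an
#: unusable noise estimate (sample SD over < 5 points).
DEFAULT_MIN_BASELINE = 5

#: Default divergence criterion in baseline-noise SDs.  The cumulative
#: noise estimate absorbs bolus samples once the scan passes the onset, so
#: overly conservative values make gradual-onset boluses undetectable;
#: 2.0 balances that against false triggers on baseline noise.
DEFAULT_K_SIGMA = 2.0

#: Relative floor guarding the divergence test on zero-variance baselines.
EPS_FLOOR_REL = 1e-6

VoxelId = Union[int, Tuple[int, int, int], None]


@dataclass(frozen=True)
class SignalTimeCourse:
    """One voxel's dynamic signal.

    Parameters
    ----------
    values
        Signal intensity per dynamic, arbitrary scanner units.
    tr_seconds
        Repetition time (temporal spacing of dynamics) in seconds.
    voxel_id
        Optional spatial identifier ``(i, j, k)`` or a flat row index.
    """

    values: np.ndarray
    tr_seconds: float
    voxel_id: VoxelId = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if values.size < 12:
            raise ValueError(f"need at least 12 dynamics, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def reversed(self) -> "SignalTimeCourse":
        return SignalTimeCourse(self.values[::-1].copy(), self.tr_seconds, self.voxel_id)


@dataclass(frozen=True)
class FirstPassSegmentation:
    """Boundaries of the bolus first pass (1-based inclusive indices).

    ``baseline_end`` is the last baseline dynamic *b*; ``postbolus_start``
    is the first post-bolus dynamic *p*; the first pass is dynamics
    ``b+1 .. p-1`` (both plateau endpoints excluded).
    """

    baseline_end: int
    postbolus_start: int
    n: int

    def __post_init__(self) -> None:
        b, p, n = self.baseline_end, self.postbolus_start, self.n
        if not (3 <= b < p <= n):
            raise ValueError(f"invalid segmentation b={b}, p={p}, n={n}")
        if p - b - 1 < 3:
            raise ValueError("first pass must contain at least 3 dynamics")

    @property
    def first_pass(self) -> range:
        """1-based inclusive first-pass dynamic indices."""
        return range(self.baseline_end + 1, self.postbolus_start)

    # 0-based slices into the values array
    @property
    def baseline_slice(self) -> slice:
        return slice(0, self.baseline_end)

    @property
    def first_pass_slice(self) -> slice:
        return slice(self.baseline_end, self.postbolus_start - 1)

    @property
    def postbolus_slice(self) -> slice:
        return slice(self.postbolus_start - 1, self.n)


def _detect_divergence(
    values: np.ndarray, min_baseline: int, k_sigma: float
) -> int:
    """Core divergence scan.  Returns the 1-based index of the last dynamic
    before the first divergence of trailing 3-point mean vs cumulative mean.
    """
    n = values.size
    if min_baseline < 3:
        raise SeriesTooShortError("series too short: min_baseline must be >= 3")
    if n < 2 * min_baseline:
        raise SeriesTooShortError(
            f"series too short: need n >= {2 * min_baseline}, got {n}"
        )
    start = max(min_baseline + 1, 3)
    # scan i (1-based) up to dynamic n-3; beyond that there is no room for
    # a first pass and a post-bolus plateau.
    for i in range(start, n - 3 + 1):
        mm = values[i - 3 : i].mean()  # trailing window: dynamics i-2 .. i
        prev = values[: i - 1]  # dynamics 1 .. i-1
        cm = prev.mean()
        sd = prev.std(ddof=1)
        floor = EPS_FLOOR_REL * abs(cm)
        if abs(mm - cm) > max(k_sigma * sd, floor):
            return i - 1
    raise NoBolusError("no bolus detected")


def detect_baseline_end(
    signal: SignalTimeCourse,
    min_baseline: int = DEFAULT_MIN_BASELINE,
    k_sigma: float = DEFAULT_K_SIGMA,
) -> int:
    """Find the last baseline dynamic *b* (1-based).

    The trailing 3-point moving mean ``mm_i`` is compared with the mean and
    sample SD of dynamics ``1..i-1``; the first ``i`` where
    ``|mm_i - cm| > max(k_sigma * sd, 1e-6 * |cm|)`` marks divergence and
    ``b = i - 1``.

    Raises
    ------
    NoBolusError
        If no divergence occurs before dynamic ``n - 3``.
    SeriesTooShortError
        If ``n < 2 * min_baseline`` or ``min_baseline < 3``.
    """
    return _detect_divergence(signal.values, min_baseline, k_sigma)


def detect_postbolus_start(
    signal: SignalTimeCourse,
    min_baseline: int = DEFAULT_MIN_BASELINE,
    k_sigma: float = DEFAULT_K_SIGMA,
) -> int:
    """Find the first post-bolus dynamic *p* (1-based).

    Identical divergence rule applied to the time-reversed series:
    ``p = n - b_rev + 1``.
    """
    b_rev = _detect_divergence(signal.values[::-1], min_baseline, k_sigma)
    return signal.n - b_rev + 1


def segment_first_pass(
    signal: SignalTimeCourse,
    min_baseline: int = DEFAULT_MIN_BASELINE,
    k_sigma: float = DEFAULT_K_SIGMA,
) -> FirstPassSegmentation:
    """Run both boundary detectors and validate the enclosed first pass.

    Raises
    ------
    DegenerateFirstPassError
        If ``p - b <= 3`` (fewer than 3 first-pass dynamics).
    """
    b = detect_baseline_end(signal, min_baseline, k_sigma)
    p = detect_postbolus_start(signal, min_baseline, k_sigma)
    if p - b <= 3:
        raise DegenerateFirstPassError(
            f"degenerate first pass: b={b}, p={p} leaves {max(p - b - 1, 0)} dynamics"
        )
    return FirstPassSegmentation(baseline_end=b, postbolus_start=p, n=signal.n)
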