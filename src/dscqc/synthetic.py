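"""Synthetic DSC-MRI signal generator with ground-truth labels.

The noiseless core is a baseline plateau, a gamma-variate first pass, and a
post-bolus plateau with tunable percentage signal recovery:

    s*(t) = s0 - A * g(t - t0) - R * G(t - t0)

where ``g`` is the gamma-variate ``t**alpha * exp(-t/beta)`` normalised to
peak 1, ``G`` is its running integral normalised to plateau 1 (a smooth
step, so the post-bolus level is approached physically rather than as a
boxcar), and ``R = A * (1 - psr_true/100)``.  A negative ``R`` produces
recovery above baseline (T1-contamination morphology).  Gaussian noise and
optional artifacts (motion spikes, extra first-pass noise, narrowed bolus,
shallow bolus) are applied on top.

Every random draw flows from a single integer seed, so identical seeds
give byte-identical outputs.

Default artifact prevalences (10% per class in cohorts) are this module's
own choice, not a literature value; override them via ``CohortSpec``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammainc

from .errors import InvalidParamsError
from .signal_model import SignalTimeCourse

ARTIFACT_CLASSES = ("none", "spikes", "first_pass_noise", "narrow", "shallow")


@dataclass(frozen=True)
class Artifacts:
    """Optional artifact injections applied to one course.

    ``spikes``: (count, amplitude) — replace random non-baseline dynamics
    with ``s0 +/- amplitude`` (motion-like).  ``first_pass_noise``: extra
    Gaussian SD added only inside the true first pass.  ``narrow``/
    ``shallow``: multiplicative scales on beta / depth (affect the truths).
    """

    spikes: Optional[Tuple[int, float]] = None
    first_pass_noise: float = 0.0
    narrow: float = 1.0
    shallow: float = 1.0


@dataclass(frozen=True)
class CourseParams:
    """Generating parameters for one synthetic signal-time course."""

    s0: float
    sigma: float
    t0: float
    alpha: float
    beta: float
    depth: float
    psr_true: float
    n_dynamics: int
    tr_seconds: float
    artifact: Artifacts = field(default_factory=Artifacts)

    def __post_init__(self) -> None:
        ok = (
            self.s0 > 0
            and self.sigma >= 0
            and self.depth >= 0
            and 0 <= self.psr_true <= 200
            and self.alpha > 0
            and self.beta > 0
            and self.n_dynamics >= 12
            and self.tr_seconds > 0
            and self.t0 >= 5 * self.tr_seconds  # at least 5 baseline dynamics
        )
        if not ok:
            raise InvalidParamsError(f"invalid params: {self}")

    def effective(self) -> "CourseParams":
        """Parameters after the narrow/shallow artifact transforms."""
        a = self.artifact
        if a.narrow == 1.0 and a.shallow == 1.0:
            return self
        return replace(self, beta=self.beta * a.narrow, depth=self.depth * a.shallow)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truths for one course, from the noiseless curve."""

    sdnr_true: float
    fwhm_true: float
    psr_true: float
    drop_true: float
    quality_label: Optional[int] = None


@dataclass(frozen=True)
class TruthRule:
    """Pure labelling rule on the truths; any criterion may be disabled."""

    sdnr_min: Optional[float] = 7.6
    fwhm_range: Optional[Tuple[float, float]] = (3.0, 19.0)
    psr_range: Optional[Tuple[float, float]] = (42.9, 130.4)

    def label(self, truth: TruthRecord) -> int:
        if self.sdnr_min is not None and not truth.sdnr_true >= self.sdnr_min:
            return 0
        if self.fwhm_range is not None and not (
            self.fwhm_range[0] <= truth.fwhm_true <= self.fwhm_range[1]
        ):
            return 0
        if self.psr_range is not None and not (
            self.psr_range[0] <= truth.psr_true <= self.psr_range[1]
        ):
            return 0
        return 1


def _gamma_peak1(tau: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate normalised to peak 1 at tau = alpha*beta; 0 for tau<=0."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / (alpha * beta)
    out[pos] = np.power(x, alpha) * np.exp(alpha * (1.0 - x))
    return out


def _gamma_step(tau: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Running integral of the gamma-variate, normalised to plateau 1."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = gammainc(alpha + 1.0, tau[pos] / beta)
    return out


def noiseless_curve(params: CourseParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the artifact-transformed noiseless curve at times ``t``."""
    p = params.effective()
    tau = np.asarray(t, dtype=float) - p.t0
    A = p.depth
    R = A * (1.0 - p.psr_true / 100.0)
    return p.s0 - A * _gamma_peak1(tau, p.alpha, p.beta) - R * _gamma_step(tau, p.alpha, p.beta)


def _truths(params: CourseParams) -> TruthRecord:
    p = params.effective()
    duration = p.n_dynamics * p.tr_seconds
    t = np.linspace(0.0, duration, 4000)
    s = noiseless_curve(params, t)
    m = int(np.argmin(s))
    drop = float(p.s0 - s[m])
    if drop <= 0:
        return TruthRecord(
            sdnr_true=0.0, fwhm_true=np.nan, psr_true=p.psr_true, drop_true=0.0
        )
    half = p.s0 - drop / 2.0
    below = s < half
    # nearest crossings around the minimum, linearly interpolated
    left = None
    for j in range(m, 0, -1):
        if below[j] and not below[j - 1]:
            frac = (s[j - 1] - half) / (s[j - 1] - s[j])
            left = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    right = None
    for j in range(m, len(t) - 1):
        if below[j] and not below[j + 1]:
            frac = (half - s[j]) / (s[j + 1] - s[j])
            right = t[j] + frac * (t[j + 1] - t[j])
            break
    fwhm_true = float(right - left) if left is not None and right is not None else np.nan
    sdnr_true = float(p.depth / p.sigma) if p.sigma > 0 else np.inf
    return TruthRecord(
        sdnr_true=sdnr_true, fwhm_true=fwhm_true, psr_true=p.psr_true, drop_true=drop
    )


def simulate_timecourse(
    params: CourseParams,
    seed: int,
    rule: Optional[TruthRule] = None,
    voxel_id=None,
) -> Tuple[SignalTimeCourse, TruthRecord]:
    """Generate one noisy course plus its truth record."""
    rng = np.random.default_rng(seed)
    p = params.effective()
    t = np.arange(params.n_dynamics) * params.tr_seconds
    s = noiseless_curve(params, t)
    values = s + rng.normal(0.0, params.sigma, size=s.size) if params.sigma > 0 else s.copy()

    a = params.artifact
    if a.first_pass_noise > 0:
        in_fp = _gamma_peak1(t - p.t0, p.alpha, p.beta) > 0.05
        values[in_fp] += rng.normal(0.0, a.first_pass_noise, size=int(in_fp.sum()))
    if a.spikes is not None:
        count, amplitude = a.spikes
        post_baseline = np.flatnonzero(t > p.t0)
        if count > 0 and post_baseline.size > 0:
            pick = rng.choice(post_baseline, size=min(count, post_baseline.size), replace=False)
            signs = rng.choice([-1.0, 1.0], size=pick.size)
            values[pick] = params.s0 + signs * amplitude

    truth = _truths(params)
    if rule is not None:
        truth = replace(truth, quality_label=rule.label(truth))
    return SignalTimeCourse(values, params.tr_seconds, voxel_id=voxel_id), truth


@dataclass
class CohortSpec:
    """Distributions from which per-course parameters are drawn.

    TR spans the multi-protocol acquisition range 1.3-4.9 s.  ``sdnr_gap``
    optionally excludes a band of true SDNR values, producing
    well-separated classes for calibration-recovery experiments.
    ``artifact_prevalence`` maps artifact class to probability; one
    artifact at most per course.
    """

    s0: float = 1000.0
    depth: float = 300.0
    sdnr_range: Tuple[float, float] = (3.0, 45.0)
    sdnr_gap: Optional[Tuple[float, float]] = None
    alpha_range: Tuple[float, float] = (1.5, 3.0)
    beta_range_seconds: Tuple[float, float] = (0.8, 2.8)
    beta_min_tr_factor: float = 0.7  # keep the first pass sampled by >= a few dynamics
    psr_draw_range: Tuple[float, float] = (45.0, 135.0)
    tr_range: Tuple[float, float] = (1.3, 2.4)
    n_dynamics: int = 60
    baseline_dynamics: int = 8
    artifact_prevalence: Dict[str, float] = field(default_factory=lambda: {
        "spikes": 0.05, "first_pass_noise": 0.05, "narrow": 0.05, "shallow": 0.05,
    })
    spike_count: int = 2
    spike_amplitude_rel: float = 0.6   # x depth
    first_pass_noise_rel: float = 3.0  # x sigma
    narrow_scale: float = 0.25
    shallow_scale: float = 0.2
    rule: TruthRule = field(default_factory=TruthRule)
    target_pass_rate: float = 0.7  # documentation anchor for the defaults


def _draw_params(spec: CohortSpec, rng: np.random.Generator) -> CourseParams:
    tr = float(rng.uniform(*spec.tr_range))
    lo, hi = spec.sdnr_range
    while True:
        sdnr_true = float(rng.uniform(lo, hi))
        if spec.sdnr_gap is None or not (spec.sdnr_gap[0] < sdnr_true < spec.sdnr_gap[1]):
            break
    sigma = spec.depth / sdnr_true
    alpha = float(rng.uniform(*spec.alpha_range))
    beta = float(rng.uniform(*spec.beta_range_seconds))
    beta = max(beta, spec.beta_min_tr_factor * tr)
    psr_true = float(rng.uniform(*spec.psr_draw_range))

    u = rng.uniform()
    artifact = Artifacts()
    name = "none"
    acc = 0.0
    for cls, p in spec.artifact_prevalence.items():
        acc += p
        if u < acc:
            name = cls
            break
    if name == "spikes":
        artifact = Artifacts(spikes=(spec.spike_count, spec.spike_amplitude_rel * spec.depth))
    elif name == "first_pass_noise":
        artifact = Artifacts(first_pass_noise=spec.first_pass_noise_rel * sigma)
    elif name == "narrow":
        artifact = Artifacts(narrow=spec.narrow_scale)
    elif name == "shallow":
        artifact = Artifacts(shallow=spec.shallow_scale)

    return CourseParams(
        s0=spec.s0, sigma=sigma, t0=spec.baseline_dynamics * tr,
        alpha=alpha, beta=beta, depth=spec.depth, psr_true=psr_true,
        n_dynamics=spec.n_dynamics, tr_seconds=tr, artifact=artifact,
    )


def _artifact_name(a: Artifacts) -> str:
    if a.spikes is not None:
        return "spikes"
    if a.first_pass_noise > 0:
        return "first_pass_noise"
    if a.narrow != 1.0:
        return "narrow"
    if a.shallow != 1.0:
        return "shallow"
    return "none"


def simulate_cohort(
    spec: CohortSpec,
    n: int,
    seed: int,
) -> Tuple[List[SignalTimeCourse], pd.DataFrame]:
    """Generate ``n`` labelled courses plus the truth table.

    The truth table carries every generating parameter, the truths, and the
    label from ``spec.rule`` so labels are re-derivable.
    """
    if n < 20:
        raise InvalidParamsError("cohort needs n >= 20")
    rng = np.random.default_rng(seed)
    courses: List[SignalTimeCourse] = []
    rows = []
    for i in range(n):
        params = _draw_params(spec, rng)
        course_seed = int(rng.integers(0, 2**31 - 1))
        course, truth = simulate_timecourse(params, course_seed, rule=spec.rule, voxel_id=i)
        courses.append(course)
        rows.append({
            "course_id": i,
            "tr_seconds": params.tr_seconds,
            "n_dynamics": params.n_dynamics,
            "s0": params.s0,
            "sigma": params.sigma,
            "t0": params.t0,
            "alpha": params.alpha,
            "beta": params.beta,
            "depth": params.depth,
            "artifact": _artifact_name(params.artifact),
            "sdnr_true": truth.sdnr_true,
            "fwhm_true": truth.fwhm_true,
            "psr_true": truth.psr_true,
            "drop_true": truth.drop_true,
            "qr_label": truth.quality_label,
        })
    return courses, pd.DataFrame(rows)


def courses_to_frame(courses: List[SignalTimeCourse]) -> pd.DataFrame:
    """One row per course: course_id, tr_seconds, then the dynamics."""
    n_max = max(c.n for c in courses)
    rows = []
    for i, c in enumerate(courses):
        row = {"course_id": i, "tr_seconds": c.tr_seconds}
        for d in range(n_max):
            row[f"d{d + 1}"] = c.values[d] if d < c.n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_recovery_spec(sdnr_boundary: float = 8.0) -> CohortSpec:
    """Cohort with well-separated classes labelled by true SDNR only.

    Classes are split by ``sdnr_boundary`` with an excluded band around it,
    long baselines (stable noise estimate) and broad, well-sampled boluses,
    so calibration should recover a threshold near the boundary.
    """
    return CohortSpec(
        sdnr_range=(4.5, 18.0),
        sdnr_gap=(sdnr_boundary - 0.5, sdnr_boundary + 4.0),
        alpha_range=(1.5, 2.2),
        beta_range_seconds=(2.0, 3.5),
        beta_min_tr_factor=1.2,
        tr_range=(1.3, 2.0),
        psr_draw_range=(70.0, 110.0),
        baseline_dynamics=20,
        n_dynamics=80,
        artifact_prevalence={},
        rule=TruthRule(sdnr_min=sdnr_boundary, fwhm_range=None, psr_range=None),
    )


def separable_feature_table(
    n: int = 400,
    separation: float = 4.0,
    pass_rate: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Two Gaussian feature clouds separated by ``separation`` SDs.

    Direct feature-space generator for classifier sanity checks; scales
    mimic the four quality measures.
    """
    rng = np.random.default_rng(seed)
    n1 = int(round(n * pass_rate))
    n0 = n - n1
    sd = np.array([2.0, 0.004, 1.2, 9.0])
    mean0 = np.array([6.0, 0.030, 2.5, 35.0])
    mean1 = mean0 + separation * sd * np.array([1.0, -1.0, 1.0, 1.0])
    X1 = rng.normal(mean1, sd, size=(n1, 4))
    X0 = rng.normal(mean0, sd, size=(n0, 4))
    df = pd.DataFrame(
        np.vstack([X1, X0]), columns=["sdnr", "rmse_norm", "fwhm_s", "psr_pct"]
    )
    df["qr_label"] = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


@dataclass
class PhantomSpec:
    """4D phantom: PSR varies along x, bolus width along y.

    The lower interior rows use a widened bolus whose true FWHM falls
    outside the default acceptance range; noiseless by default so that the
    end-to-end pipeline is exact.
    """

    s0: float = 1000.0
    sigma: float = 0.0
    depth: float = 300.0
    alpha: float = 2.0
    beta_in: float = 1.5
    beta_out: float = 7.0
    tr_seconds: float = 1.5
    n_dynamics: int = 80
    baseline_dynamics: int = 8
    psr_low: float = 60.0
    psr_high: float = 120.0
    rule: TruthRule = field(default_factory=lambda: TruthRule(sdnr_min=None))


def phantom_arrays(
    spec: PhantomSpec,
    grid: Tuple[int, int, int],
    seed: int,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the 4D signal array, 3D truth map and per-voxel truth table.

    A one-voxel zero-signal border surrounds the varying interior (truth
    map NaN there).
    """
    nx, ny, nz = grid
    if nx < 4 or ny < 4 or nz < 1:
        raise InvalidParamsError("grid must be at least 4x4x1")
    rng = np.random.default_rng(seed)
    vol = np.zeros((nx, ny, nz, spec.n_dynamics), dtype=float)
    truth_map = np.full((nx, ny, nz), np.nan)
    rows = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                interior = 0 < x < nx - 1 and 0 < y < ny - 1
                if not interior:
                    continue
                fx = (x - 1) / max(nx - 3, 1)
                psr = spec.psr_low + fx * (spec.psr_high - spec.psr_low)
                beta = spec.beta_out if (y - 1) < (ny - 2) // 2 else spec.beta_in
                params = CourseParams(
                    s0=spec.s0, sigma=spec.sigma,
                    t0=spec.baseline_dynamics * spec.tr_seconds,
                    alpha=spec.alpha, beta=beta, depth=spec.depth,
                    psr_true=psr, n_dynamics=spec.n_dynamics,
                    tr_seconds=spec.tr_seconds,
                )
                course, truth = simulate_timecourse(
                    params, int(rng.integers(0, 2**31 - 1)), rule=spec.rule,
                    voxel_id=(x, y, z),
                )
                vol[x, y, z, :] = course.values
                truth_map[x, y, z] = truth.quality_label
                rows.append({
                    "i": x, "j": y, "k": z,
                    "beta": beta,
                    "sdnr_true": truth.sdnr_true,
                    "fwhm_true": truth.fwhm_true,
                    "psr_true": truth.psr_true,
                    "qr_label": truth.quality_label,
                })
    return vol, truth_map, pd.DataFrame(rows)


def write_phantom(
    spec: PhantomSpec,
    grid: Tuple[int, int, int],
    seed: int,
    path,
    truth_path=None,
    truth_csv_path=None,
) -> None:
    """Write the phantom as a 4D NIfTI (TR in the 4th pixdim) plus truths."""
    import nibabel as nib

    vol, truth_map, truth_df = phantom_arrays(spec, grid, seed)
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, spec.tr_seconds))
    nib.save(img, str(path))
    if truth_path is not None:
        nib.save(nib.Nifti1Image(truth_map, affine), str(truth_path))
    if truth_csv_path is not None:
        truth_df.to_csv(truth_csv_path, index=False)
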