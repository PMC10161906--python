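import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscqc import (
    CourseParams,
    SignalTimeCourse,
    extract_features,
    features_to_frame,
    fit_gamma_variate,
    fwhm,
    psr,
    sdnr,
    signal_drop,
    simulate_timecourse,
)
from dscqc.errors import DegenerateBaselineError, FirstPassTooShortError, ZeroSignalDropError
from dscqc.signal_model import FirstPassSegmentation, segment_first_pass


@pytest.fixture
def example_seg(example_signal):
    return segment_first_pass(example_signal, min_baseline=3)


class TestSignalDrop:
    def test_worked_example(self, example_signal, example_seg):
        assert signal_drop(example_signal, example_seg) == pytest.approx(100 - 200 / 3, abs=1e-9)

    def test_flat_signal_zero_drop(self):
        s = SignalTimeCourse(np.full(15, 100.0), 1.0)
        seg = FirstPassSegmentation(baseline_end=5, postbolus_start=11, n=15)
        assert signal_drop(s, seg) == 0.0

    def test_offset_invariance(self, example_signal, example_seg):
        shifted = SignalTimeCourse(example_signal.values + 500, 1.0)
        assert signal_drop(shifted, example_seg) == pytest.approx(
            signal_drop(example_signal, example_seg)
        )


class TestSdnr:
    def test_worked_example(self, noisy_baseline_signal):
        seg = segment_first_pass(noisy_baseline_signal, min_baseline=3)
        # baseline sample SD is exactly 1, drop is 33.333
        assert sdnr(noisy_baseline_signal, seg) == pytest.approx(100 / 3, abs=1e-9)

    def test_degenerate_baseline(self, example_signal, example_seg):
        with pytest.raises(DegenerateBaselineError):
            sdnr(example_signal, example_seg)

    def test_scale_invariance(self, noisy_baseline_signal):
        seg = segment_first_pass(noisy_baseline_signal, min_baseline=3)
        scaled = SignalTimeCourse(noisy_baseline_signal.values * 7.5, 1.0)
        assert sdnr(scaled, seg) == pytest.approx(sdnr(noisy_baseline_signal, seg))


def _gamma_signal(c=100.0, K=5.0, alpha=1.5, beta=2.0, n=30, b=6, tr=1.0, noise=None, seed=0):
    values = np.full(n, c)
    for i in range(b, n):
        t = (i + 1 - b) * tr
        values[i] = c - K * t**alpha * np.exp(-t / beta)
    if noise:
        values = values + np.random.default_rng(seed).normal(0, noise, n)
    return SignalTimeCourse(values, tr)


class TestGammaFit:
    def test_noiseless_recovery(self):
        s = _gamma_signal()
        seg = segment_first_pass(s, min_baseline=3)
        fit = fit_gamma_variate(s, seg)
        assert fit.converged
        assert fit.K == pytest.approx(5.0, rel=1e-4)
        assert fit.alpha == pytest.approx(1.5, rel=1e-4)
        assert fit.beta == pytest.approx(2.0, rel=1e-4)
        assert fit.rmse_norm < 1e-6

    def test_noise_increases_rmse(self):
        clean = _gamma_signal()
        seg = segment_first_pass(clean, min_baseline=3)
        noisy = _gamma_signal(noise=2.0)
        fit_clean = fit_gamma_variate(clean, seg)
        fit_noisy = fit_gamma_variate(noisy, seg)
        assert fit_noisy.rmse_norm > fit_clean.rmse_norm

    def test_scale_invariance(self):
        s = _gamma_signal(noise=1.0)
        seg = segment_first_pass(s, min_baseline=3)
        scaled = SignalTimeCourse(s.values * 3.0, 1.0)
        assert fit_gamma_variate(scaled, seg).rmse_norm == pytest.approx(
            fit_gamma_variate(s, seg).rmse_norm, rel=1e-6
        )

    def test_first_pass_too_short(self):
        v = np.array([100.0] * 5 + [70, 60, 70] + [100.0] * 7)
        s = SignalTimeCourse(v, 1.0)
        seg = FirstPassSegmentation(baseline_end=5, postbolus_start=9, n=15)
        with pytest.raises(FirstPassTooShortError):
            fit_gamma_variate(s, seg)

    def test_best_fit_beats_grid_oracle(self):
        # optimality spot-check: no coarse-grid candidate does better
        s = _gamma_signal(K=20.0, noise=1.5, seed=5)
        seg = segment_first_pass(s, min_baseline=3)
        fit = fit_gamma_variate(s, seg)
        b, p = seg.baseline_end, seg.postbolus_start
        t = (np.arange(b + 1, p) - b) * s.tr_seconds
        y = s.values[seg.first_pass_slice]
        c = s.values[: b].mean()
        best_grid = np.inf
        for K in np.linspace(5, 40, 8):
            for alpha in np.linspace(0.5, 3.0, 8):
                for beta in np.linspace(0.5, 5.0, 8):
                    r = y - (c - K * t**alpha * np.exp(-t / beta))
                    best_grid = min(best_grid, np.sqrt(np.mean(r**2)))
        area = np.trapezoid(c - y, t)
        assert fit.rmse_norm <= best_grid / area + 1e-12


class TestFwhm:
    def test_worked_example(self, example_signal, example_seg):
        # half-level 83.333; crossings at dynamics 6.333 and 9.667
        assert fwhm(example_signal, example_seg) == pytest.approx(10 / 3, abs=1e-9)

    def test_linear_in_tr(self, example_signal, example_seg):
        slow = SignalTimeCourse(example_signal.values, 2.0)
        assert fwhm(slow, example_seg) == pytest.approx(20 / 3, abs=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(
        a=st.floats(min_value=0.01, max_value=50.0),
        c=st.floats(min_value=-1e3, max_value=1e3),
    )
    def test_affine_invariance(self, a, c):
        values = np.array([100.0] * 5 + [90, 70, 60, 70, 90] + [100.0] * 5)
        s = SignalTimeCourse(values, 1.0)
        seg = FirstPassSegmentation(baseline_end=5, postbolus_start=11, n=15)
        t = SignalTimeCourse(a * values + c, 1.0)
        assert fwhm(t, seg) == pytest.approx(fwhm(s, seg), rel=1e-9)


class TestPsr:
    def test_full_recovery(self, example_signal, example_seg):
        assert psr(example_signal, example_seg) == pytest.approx(100.0, abs=1e-9)

    def test_partial_recovery(self, plateau90_signal):
        seg = segment_first_pass(plateau90_signal, min_baseline=3)
        # drop 33.333 unchanged, recovery 23.333 -> 70%
        assert psr(plateau90_signal, seg) == pytest.approx(70.0, abs=1e-9)

    def test_overshoot_above_100(self):
        v = np.array([100.0] * 5 + [90, 70, 60, 70, 90] + [110.0] * 5)
        s = SignalTimeCourse(v, 1.0)
        seg = FirstPassSegmentation(baseline_end=5, postbolus_start=11, n=15)
        assert psr(s, seg) > 100.0

    def test_zero_drop_error(self):
        s = SignalTimeCourse(np.full(15, 100.0), 1.0)
        seg = FirstPassSegmentation(baseline_end=5, postbolus_start=11, n=15)
        with pytest.raises(ZeroSignalDropError):
            psr(s, seg)


class TestExtractFeatures:
    def test_composition(self, noisy_baseline_signal):
        f = extract_features(noisy_baseline_signal, min_baseline=3)
        assert f.valid
        assert f.sdnr == pytest.approx(100 / 3, abs=1e-9)
        assert f.fwhm_seconds == pytest.approx(10 / 3, abs=1e-9)
        assert f.psr_percent == pytest.approx(100.0, abs=1e-9)
        assert np.isfinite(f.rmse_norm)

    def test_constant_signal_all_invalid(self):
        f = extract_features(SignalTimeCourse(np.full(20, 100.0), 1.0))
        assert not f.valid
        assert all(not v for v in f.flags.values())
        assert "no bolus detected" in f.reason

    def test_batch_order_preserved(self, noisy_baseline_signal):
        courses = []
        for i in range(5):
            courses.append(SignalTimeCourse(
                noisy_baseline_signal.values + i * 10, 1.0, voxel_id=i,
            ))
        frame = features_to_frame([extract_features(c, min_baseline=3) for c in courses])
        assert list(frame["voxel_id"]) == [str(i) for i in range(5)]

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(min_value=0.05, max_value=20.0),
        c=st.floats(min_value=-500.0, max_value=500.0),
    )
    def test_all_measures_affine_invariant(self, a, c):
        values = np.array([101.0, 99, 101, 99, 100] + [90, 70, 60, 70, 90] + [100.0] * 5)
        f0 = extract_features(SignalTimeCourse(values, 1.0), min_baseline=3)
        f1 = extract_features(SignalTimeCourse(a * values + c, 1.0), min_baseline=3)
        assert f1.sdnr == pytest.approx(f0.sdnr, rel=1e-6)
        assert f1.fwhm_seconds == pytest.approx(f0.fwhm_seconds, rel=1e-6)
        assert f1.psr_percent == pytest.approx(f0.psr_percent, rel=1e-6)
        assert f1.rmse_norm == pytest.approx(f0.rmse_norm, rel=1e-3)

    def test_sdnr_psr_tr_invariant(self, noisy_baseline_signal):
        f1 = extract_features(noisy_baseline_signal, min_baseline=3)
        f2 = extract_features(
            SignalTimeCourse(noisy_baseline_signal.values, 3.0), min_baseline=3
        )
        assert f2.sdnr == pytest.approx(f1.sdnr)
        assert f2.psr_percent == pytest.approx(f1.psr_percent)
        assert f2.fwhm_seconds == pytest.approx(3 * f1.fwhm_seconds)


class TestSamplingDistribution:
    def test_mean_measured_sdnr_unbiased(self):
        # depth 30, sigma 3 -> true SDNR 10; broad well-sampled bolus and a
        # sensitive divergence setting keep the baseline uncontaminated
        params = CourseParams(
            s0=1000.0, sigma=3.0, t0=20.0, alpha=2.5, beta=4.0, depth=30.0,
            psr_true=95.0, n_dynamics=70, tr_seconds=1.0,
        )
        vals = []
        for seed in range(500):
            course, _ = simulate_timecourse(params, seed)
            f = extract_features(course, k_sigma=1.7)
            if f.valid:
                vals.append(f.sdnr)
        vals = np.asarray(vals)
        assert len(vals) > 450
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 10.0) < 3 * se
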