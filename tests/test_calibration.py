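import numpy as np
import pandas as pd
import pytest

from dscqc import (
    ThresholdSet,
    apply_thresholds,
    calibrate_kfold,
    crossing_threshold,
    default_thresholds,
    range_thresholds,
)
from dscqc.calibration import stratified_folds
from dscqc.errors import InsufficientDataError, NoPassingExamplesError, SingleClassError


def _crossing_oracle(values, labels, orientation):
    """Brute-force scan over candidates, independent of the implementation."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    best = None
    for theta in sorted(set(v)):
        pred = v >= theta if orientation == "higher_is_better" else v <= theta
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        key = (abs(sens - spec), -(sens + spec), theta)
        if best is None or key < best:
            best = key
    return best


class TestCrossingThreshold:
    def test_worked_example(self):
        theta = crossing_threshold([10, 12, 14, 2, 4, 20], [1, 1, 1, 0, 0, 0],
                                   "higher_is_better")
        assert theta == 12.0

    def test_perfect_separation_tie_break(self):
        theta = crossing_threshold([8, 9, 10, 1, 2, 3], [1, 1, 1, 0, 0, 0],
                                   "higher_is_better")
        assert theta == 8.0

    def test_orientation_flip_symmetry(self):
        values = [10, 12, 14, 2, 4, 20]
        labels = [1, 1, 1, 0, 0, 0]
        lo = crossing_threshold([-v for v in values], labels, "lower_is_better")
        hi = crossing_threshold(values, labels, "higher_is_better")
        assert lo == -hi

    def test_single_class_error(self):
        with pytest.raises(SingleClassError):
            crossing_threshold([1, 2, 3], [1, 1, 1], "higher_is_better")

    def test_optimality_against_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 40))
            v = rng.normal(10, 3, n).round(2)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            for orient in ("higher_is_better", "lower_is_better"):
                theta = crossing_threshold(v, y, orient)
                diff, negsum, best_theta = _crossing_oracle(v, y, orient)
                pred = v >= theta if orient == "higher_is_better" else v <= theta
                sens = pred[y == 1].mean()
                spec = (~pred[y == 0]).mean()
                assert abs(sens - spec) == pytest.approx(diff)
                assert theta == best_theta


class TestRangeThresholds:
    def test_worked_example(self):
        lo, hi = range_thresholds([1.8, 3, 7, 19, 25], [0, 1, 1, 1, 0])
        assert (lo, hi) == (3.0, 19.0)

    def test_all_pass(self):
        assert range_thresholds([2, 5, 9], [1, 1, 1]) == (2.0, 9.0)

    def test_single_passing_value(self):
        assert range_thresholds([2, 5, 9], [0, 1, 0]) == (5.0, 5.0)

    def test_no_passing_examples(self):
        with pytest.raises(NoPassingExamplesError):
            range_thresholds([1, 2], [0, 0])

    def test_never_rejects_training_pass(self, rng):
        v = rng.uniform(0, 30, 60)
        y = rng.integers(0, 2, 60)
        y[0] = 1
        lo, hi = range_thresholds(v, y)
        passing = v[y == 1]
        assert np.all((passing >= lo) & (passing <= hi))


class TestApplyThresholds:
    @pytest.fixture
    def shipped(self):
        return default_thresholds()

    def test_sdnr_pass(self, shipped):
        row = {"sdnr": 100 / 3, "rmse_norm": 0.01, "fwhm_s": 5.0, "psr_pct": 90.0}
        assert apply_thresholds(row, shipped, "sdnr")[0] == 1

    def test_fwhm_outside_range_fails(self, shipped):
        row = {"sdnr": 10.0, "rmse_norm": 0.01, "fwhm_s": 2.0, "psr_pct": 90.0}
        assert apply_thresholds(row, shipped, "fwhm_s")[0] == 0

    def test_psr_boundary_inclusive(self, shipped):
        row = {"sdnr": 10.0, "rmse_norm": 0.01, "fwhm_s": 5.0, "psr_pct": 130.4}
        assert apply_thresholds(row, shipped, "psr_pct")[0] == 1

    def test_invalid_feature_fails_with_reason(self, shipped):
        row = {"sdnr": np.nan, "rmse_norm": 0.01, "fwhm_s": 5.0, "psr_pct": 90.0}
        label, reason = apply_thresholds(row, shipped, "sdnr")
        assert label == 0 and reason

    def test_shipped_defaults_match_published(self, shipped):
        assert shipped.sdnr_min == 7.6
        assert shipped.rmse_max == 0.019
        assert shipped.fwhm_range == (3.0, 19.0)
        assert shipped.psr_range == (42.9, 130.4)


def _toy_table(n=200, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    sdnr = np.where(y == 1, rng.normal(14, 2, n), rng.normal(5, 2, n)) * scale
    return pd.DataFrame({
        "sdnr": sdnr,
        "rmse_norm": np.where(y == 1, rng.normal(0.01, 0.003, n), rng.normal(0.03, 0.005, n)),
        "fwhm_s": np.where(y == 1, rng.normal(8, 2, n), rng.normal(8, 6, n)).clip(0.1),
        "psr_pct": np.where(y == 1, rng.normal(90, 10, n), rng.normal(90, 50, n)).clip(0),
        "qr_label": y,
    })


class TestStratifiedFolds:
    def test_partition_and_balance(self):
        y = np.array([1] * 70 + [0] * 30)
        folds = stratified_folds(y, 10, seed=4)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(100))
        for f in folds:
            assert np.sum(y[f] == 1) == 7
            assert np.sum(y[f] == 0) == 3

    def test_insufficient_class(self):
        y = np.array([1] * 5 + [0] * 50)
        with pytest.raises(InsufficientDataError):
            stratified_folds(y, 10, seed=0)


class TestCalibrateKfold:
    def test_determinism(self):
        table = _toy_table()
        ts1, _ = calibrate_kfold(table, k=10, seed=3)
        ts2, _ = calibrate_kfold(table, k=10, seed=3)
        assert ts1.to_dict() == ts2.to_dict()

    def test_insufficient_positives(self):
        table = _toy_table(n=60)
        table["qr_label"] = [1] * 5 + [0] * 55
        with pytest.raises(InsufficientDataError):
            calibrate_kfold(table, k=10, seed=0)

    def test_scale_equivariance(self):
        ts1, _ = calibrate_kfold(_toy_table(scale=1.0), k=5, seed=3)
        ts2, _ = calibrate_kfold(_toy_table(scale=4.0), k=5, seed=3)
        assert ts2.sdnr_min == pytest.approx(4.0 * ts1.sdnr_min)

    def test_headline_is_fold_mean(self):
        ts, _ = calibrate_kfold(_toy_table(), k=5, seed=3)
        assert ts.sdnr_min == pytest.approx(np.mean([e["sdnr"] for e in ts.per_fold]))
        assert ts.k == 5 and len(ts.per_fold) == 5

    def test_yaml_round_trip(self, tmp_path):
        ts, _ = calibrate_kfold(_toy_table(), k=5, seed=3)
        path = tmp_path / "th.yaml"
        ts.to_yaml(path)
        loaded = ThresholdSet.from_yaml(path)
        assert loaded.sdnr_min == ts.sdnr_min
        assert loaded.fwhm_range == ts.fwhm_range
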