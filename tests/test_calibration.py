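"""Replicate statistics, OLS calibration, step estimation, pump check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipqc import calibration as cal
from tipqc.calibration import (
    CubeLinearCalibrator,
    DegenerateDesignError,
    InsufficientReplicatesError,
    ReplicateTable,
    check_pump,
    deviation_stats,
    fit_cube_linear,
    ols_fit,
    replicate_stats,
    summary_stats,
)


def normal_equations_ols(x, y):
    """Independent oracle: solve X'X beta = X'y directly."""
    X = np.column_stack([np.asarray(x, float), np.ones(len(x))])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - np.mean(y)) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


class TestReplicateTable:
    def test_rejects_nonpositive_steps_and_values(self):
        with pytest.raises(ValueError, match="positive"):
            ReplicateTable(np.array([0.0, 40.0]), [np.array([1.0]), np.array([2.0])])
        with pytest.raises(ValueError, match="non-positive"):
            ReplicateTable(np.array([40.0]), [np.array([1.0, -2.0])])

    def test_duplicate_step_rows_merge_as_replicates(self):
        import pandas as pd

        df = pd.DataFrame({"steps": [40, 40, 80], "rep1": [5.0, 5.2, 11.0]})
        t = ReplicateTable.from_frame(df)
        assert list(t.steps) == [40.0, 80.0]
        assert len(t.values[0]) == 2


class TestReplicateStats:
    def test_cv_in_percent_from_replicates(self):
        # five replicates constructed to have mean 5.28, sample std 0.26
        reps = np.array([5.28, 5.28, 5.28 - 0.26 * np.sqrt(2), 5.28 + 0.26 * np.sqrt(2), 5.28])
        t = ReplicateTable(np.array([40.0]), [reps])
        stats = replicate_stats(t)
        assert stats.loc[0, "mean"] == pytest.approx(5.28)
        assert stats.loc[0, "std"] == pytest.approx(0.26)
        assert round(stats.loc[0, "cv_percent"], 1) == 4.9

    def test_identical_replicates_give_zero_cv(self):
        t = ReplicateTable(np.array([40.0]), [np.full(5, 7.0)])
        assert replicate_stats(t).loc[0, "cv_percent"] == 0.0

    def test_single_replicate_std_is_an_error(self):
        t = ReplicateTable(np.array([40.0, 80.0]), [np.array([5.0]), np.array([1.0, 2.0])])
        with pytest.raises(InsufficientReplicatesError):
            replicate_stats(t)

    @pytest.mark.parametrize(
        "mean,std,expected", [(5.28, 0.26, 4.9), (72.0, 1.87, 2.6), (11.46, 0.34, 3.0)]
    )
    def test_cv_from_published_summaries(self, mean, std, expected):
        assert round(summary_stats([mean], [std])[0], 1) == expected


class TestOlsFit:
    def test_exact_line_recovered(self):
        x = np.arange(1.0, 6.0)
        slope, intercept, r2 = ols_fit(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            ols_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x = rng.uniform(-50, 50, n)
        if np.ptp(x) == 0:
            x[0] += 1.0
        y = rng.uniform(-2, 2) * x + rng.normal(0, 5, n)
        got = ols_fit(x, y)
        want = normal_equations_ols(x, y)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-100, 100), c=st.floats(0.1, 10), d=st.floats(-100, 100)
    )
    @settings(max_examples=40)
    def test_r_squared_invariant_under_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, 12)
        y = 3 * x + rng.normal(0, 20, 12)
        _, _, r2 = ols_fit(x, y)
        _, _, r2_scaled = ols_fit(a * x + b, c * y + d)
        assert r2_scaled == pytest.approx(r2, rel=1e-9)


class TestCubeLinearCalibrator:
    def test_two_point_table_fits_exactly(self):
        t = ReplicateTable(np.array([100.0, 200.0]), [np.array([50.0]), np.array([63.0])])
        model = fit_cube_linear(t)
        assert model.r_squared_ == pytest.approx(1.0)
        assert model.transform == "cubed volume length"

    def test_identity_calibration_estimates_cube(self):
        model = CubeLinearCalibrator()
        model.slope_, model.intercept_, model.r_squared_ = 1.0, 0.0, 1.0
        assert model.estimate_steps(4.0) == pytest.approx(64.0)

    @given(
        a=st.floats(10, 1e5), b=st.floats(-1e4, 1e4), s=st.floats(40, 640)
    )
    def test_round_trip_inversion(self, a, b, s):
        model = CubeLinearCalibrator()
        model.slope_, model.intercept_, model.r_squared_ = a, b, 1.0
        L = np.cbrt(a * s + b) if a * s + b >= 0 else None
        if L is None:
            return
        assert model.estimate_steps(L) == pytest.approx(s, rel=1e-9, abs=1e-6)

    def test_zero_slope_cannot_invert(self):
        model = CubeLinearCalibrator()
        model.slope_, model.intercept_, model.r_squared_ = 0.0, 1.0, 0.0
        with pytest.raises(ZeroDivisionError):
            model.estimate_steps(5.0)

    def test_negative_estimates_returned_as_is(self):
        model = CubeLinearCalibrator()
        model.slope_, model.intercept_, model.r_squared_ = 100.0, 5000.0, 1.0
        assert model.estimate_steps(1.0) < 0

    def test_json_round_trip(self, tmp_path):
        t = ReplicateTable(np.array([100.0, 200.0, 300.0]), [np.array([50.0]), np.array([63.0]), np.array([72.0])])
        model = fit_cube_linear(t)
        path = tmp_path / "cal.json"
        model.save(path)
        loaded = CubeLinearCalibrator.load(path)
        assert loaded.slope_ == model.slope_
        assert loaded.estimate_steps(60.0) == pytest.approx(model.estimate_steps(60.0))

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        model = CubeLinearCalibrator(transform="mass")
        assert model.get_params() == {"transform": "mass"}
        assert clone(model).transform == "mass"

    def test_parameter_recovery_within_three_standard_errors(self):
        """Calibrating on noisy cube-law sweeps recovers the generating slope."""
        from scipy import stats as sps

        a_true, b_true = 30000.0, -1.5e6
        steps = np.arange(40.0, 641.0, 40.0)
        misses = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lengths = np.cbrt(a_true * steps + b_true + rng.normal(0, 2e5, steps.size))
            res = sps.linregress(steps, lengths**3)
            if abs(res.slope - a_true) > 3 * res.stderr:
                misses += 1
        # 3 sigma two-sided: expect ~0.3% misses; allow a small margin
        assert misses <= 3


class TestDeviationStats:
    def test_published_worked_example(self):
        dev, rel = 25.3, deviation_stats(40.0, [40.0 + 25.3])[1]
        assert round(rel, 1) == 63.2
        assert deviation_stats(40.0, [40.0 + dev])[0] == pytest.approx(dev)

    def test_perfect_estimates_have_zero_deviation(self):
        assert deviation_stats(100.0, [100.0, 100.0]) == (0.0, 0.0)

    def test_single_estimate_is_absolute_error(self):
        dev, _ = deviation_stats(100.0, [93.0])
        assert dev == pytest.approx(7.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=40)
    def test_rms_about_truth_dominates_std_about_mean(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.normal(110, 5, 8)
        dev, _ = deviation_stats(100.0, est)
        spread = float(np.sqrt(np.mean((est - est.mean()) ** 2)))
        assert dev >= spread - 1e-12
        # algebraic identity: dev^2 = spread^2 + bias^2
        assert dev**2 == pytest.approx(spread**2 + (est.mean() - 100.0) ** 2)

    def test_nonpositive_true_steps_rejected(self):
        with pytest.raises(ValueError):
            deviation_stats(0.0, [1.0])


class TestCheckPump:
    @pytest.fixture
    def identity_model(self):
        m = CubeLinearCalibrator()
        m.slope_, m.intercept_, m.r_squared_ = 1.0, 0.0, 1.0
        return m

    def test_exact_estimate_passes_any_bound(self, identity_model):
        res = check_pump(64.0, 4.0, identity_model, "relative", 0.001)
        assert res.passed and res.deviation == 0.0

    def test_five_percent_boundary_is_inclusive(self, identity_model):
        # estimate 380 at commanded 400 is exactly 5.0%; strict > means pass
        res = check_pump(400.0, np.cbrt(380.0), identity_model, "relative", 5.0)
        assert res.relative_deviation_percent == pytest.approx(5.0)
        assert res.passed

    def test_beyond_bound_fails(self, identity_model):
        res = check_pump(400.0, np.cbrt(370.0), identity_model, "relative", 5.0)
        assert res.verdict == "fail"

    def test_absolute_bound_mode(self, identity_model):
        assert check_pump(100.0, np.cbrt(104.0), identity_model, "absolute", 5.0).passed
        assert not check_pump(100.0, np.cbrt(106.0), identity_model, "absolute", 5.0).passed

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            check_pump(100.0, 4.0, CubeLinearCalibrator())

    @pytest.mark.parametrize("mode,value", [("relative", 0.0), ("sideways", 5.0)])
    def test_bound_validation(self, identity_model, mode, value):
        with pytest.raises(ValueError):
            check_pump(100.0, 4.0, identity_model, mode, value)
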