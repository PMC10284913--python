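"""Spline resampling, MSE, and the two-stage fitting procedure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fractumor.fracnum import SolverConfig, Trajectory
from fractumor.fitting import (
    DEFAULT_INITS,
    FitConfig,
    compare_models,
    fit_alpha,
    fit_integer,
    mse,
    ratio_percent,
    spline_resample,
)
from fractumor.growth_models import GrowthModelSpec, ModelKind, simulate_model


def make_fixture(kind, params, alpha, v0, grid_step=0.1, horizon=18.0):
    """Noiseless dense data generated by the forward model itself."""
    spec = GrowthModelSpec(kind=kind, params=params)
    t = np.round(np.arange(0, horizon + 1e-9, grid_step), 10)
    return simulate_model(spec, alpha, v0, t, config=SolverConfig(step_h=grid_step))


class TestSplineResample:
    def test_linear_data_reproduced_exactly(self):
        t = np.array([0.0, 2.0, 5.0, 7.0, 10.0])
        y = 3.0 + 0.5 * t
        traj = spline_resample(t, y, 0.25)
        assert np.allclose(traj.volumes, 3.0 + 0.5 * traj.times, atol=1e-12)

    def test_passes_through_every_measurement(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = t**2
        traj = spline_resample(t, y, 0.5)
        for ti, yi in zip(t, y):
            j = np.argmin(np.abs(traj.times - ti))
            assert traj.volumes[j] == pytest.approx(yi, abs=1e-12)

    def test_exponential_measurements_interpolate_accurately(self):
        t = np.array([0.0, 3.0, 5.0, 8.0, 10.0])
        y = np.exp(0.109 * t)
        traj = spline_resample(t, y, 0.1)
        dev = np.max(np.abs(traj.volumes - np.exp(0.109 * traj.times)))
        assert dev < 1e-3

    def test_no_extrapolation_and_min_points(self):
        t = np.array([0.0, 2.0, 5.0, 7.0])
        traj = spline_resample(t, t + 1, 0.5)
        assert traj.times[0] == 0.0 and traj.times[-1] <= 7.0
        with pytest.raises(ValueError):
            spline_resample(t[:3], t[:3], 0.5)


class TestMse:
    def test_frozen_examples(self):
        t = np.array([0.0, 1.0])
        assert mse(Trajectory(t, np.array([1.0, 2.0])),
                   Trajectory(t, np.array([0.0, 0.0]))) == 2.5
        same = Trajectory(t, np.array([1.0, 2.0]))
        assert mse(same, same) == 0.0
        tt = np.arange(100.0)
        y = np.random.default_rng(0).uniform(1, 2, 100)
        assert mse(Trajectory(tt, y), Trajectory(tt, y + 0.1)) == pytest.approx(0.01)

    def test_misaligned_grids_rejected(self):
        a = Trajectory(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        b = Trajectory(np.array([0.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mse(a, b)

    @settings(deadline=None, max_examples=50)
    @given(
        y=st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        scale=st.floats(0.1, 10.0),
    )
    def test_permutation_invariance_and_quadratic_scaling(self, y, scale):
        y = np.asarray(y)
        yhat = y + 1.0
        t = np.arange(float(len(y)))
        base = mse(Trajectory(t, y), Trajectory(t, yhat))
        perm = np.random.default_rng(1).permutation(len(y))
        # permuting the paired samples together leaves the MSE unchanged
        assert mse(Trajectory(t, y[perm]), Trajectory(t, yhat[perm])) == (
            pytest.approx(base, rel=1e-12)
        )
        scaled = mse(Trajectory(t, scale * y), Trajectory(t, scale * yhat))
        assert scaled == pytest.approx(scale**2 * base, rel=1e-9)


class TestFitInteger:
    def test_exponential_rate_recovery(self):
        data = make_fixture("exponential", {"a": 0.109}, 1.0, 0.5)
        res = fit_integer("exponential", data, init={"a": 0.05})
        assert abs(res.model.params["a"] - 0.109) < 1e-3
        assert res.mse < 1e-8
        assert res.converged

    def test_logistic_started_at_truth_is_immediate(self):
        truth = {"a": 0.0735, "k": 2.81, "b": 3.35}
        data = make_fixture("logistic", truth, 1.0, 0.5)
        res = fit_integer("logistic", data, init=truth)
        assert res.mse < 1e-8

    def test_gompertz_recovery_from_half_scale_init(self):
        truth = {"a": 0.106, "b": 26.09, "c": 2.24}
        data = make_fixture("gompertz", truth, 1.0, 0.5)
        init = {k: 0.5 * v for k, v in truth.items()}
        res = fit_integer("gompertz", data, init=init)
        assert res.mse < 1e-6

    def test_invalid_init_rejected(self):
        data = make_fixture("exponential", {"a": 0.1}, 1.0, 0.5)
        with pytest.raises(ValueError):
            fit_integer("exponential", data, init={"a": -1.0})
        with pytest.raises(ValueError):
            fit_integer("exponential", data, init={"b": 0.1})


class TestFitAlpha:
    def test_integer_generated_data_selects_alpha_one(self):
        truth = {"a": 0.109}
        data = make_fixture("exponential", truth, 1.0, 0.5)
        res, sweep = fit_alpha("exponential", truth, data)
        assert res.alpha == 1.0
        assert sweep.alphas[-1] == 1.0

    def test_fractional_gompertz_order_recovery(self):
        truth = {"a": 0.106, "b": 26.09, "c": 2.24}
        data = make_fixture("gompertz", truth, 0.86, 0.5)
        res, sweep = fit_alpha("gompertz", truth, data)
        assert abs(res.alpha - 0.86) <= 0.01
        assert res.mse < 1e-6
        grid = np.round(sweep.alphas, 2)
        m = dict(zip(grid, sweep.mses))
        assert m[0.80] > m[0.86] < m[0.95]  # interior minimum

    def test_sweep_minimum_never_exceeds_integer_anchor(self):
        truth = {"a": 0.106, "b": 26.09, "c": 2.24}
        data = make_fixture("gompertz", truth, 0.9, 0.5)
        res, sweep = fit_alpha("gompertz", truth, data)
        assert res.mse <= sweep.mses[-1]

    def test_grid_must_contain_one(self):
        data = make_fixture("exponential", {"a": 0.1}, 1.0, 0.5)
        with pytest.raises(ValueError):
            fit_alpha("exponential", {"a": 0.1}, data,
                      alpha_grid=np.array([0.7, 0.8, 0.9]))


class TestComparison:
    def test_ratio_percent_examples(self):
        assert round(ratio_percent(0.8557, 0.2243), 2) == 26.21
        assert ratio_percent(0.5, 0.5) == 100.0
        with pytest.raises(ValueError):
            ratio_percent(-1.0, 0.5)

    def test_compare_models_fractional_never_worse(self):
        truth = {"a": 0.106, "b": 26.09, "c": 2.24}
        data = make_fixture("gompertz", truth, 0.9, 0.5)
        report = compare_models(
            {"fixture": data},
            kinds=["exponential", "gompertz"],
            config=FitConfig(maxfev=600),
        )
        assert len(report.rows) == 2
        for row in report.rows:
            assert not row.failed
            assert row.fractional_mse <= row.integer_mse + 1e-15
            assert row.ratio_percent == pytest.approx(
                100 * row.fractional_mse / row.integer_mse
            )
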