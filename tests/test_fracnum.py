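"""Fractional-calculus primitives against closed forms and high-precision oracles."""

import math

import mpmath as mp
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fractumor.fracnum import (
    FractionalOrderError,
    MittagLefflerRangeError,
    SolverConfig,
    SolverDivergenceError,
    Trajectory,
    caputo_derivative,
    mittag_leffler,
    rl_integral,
    solve_caputo_ivp,
)


def ml_reference(alpha, z, dps=50):
    """High-precision Mittag-Leffler series, the independent oracle."""
    with mp.workdps(dps):
        return float(mp.nsum(lambda k: mp.mpf(z) ** k / mp.gamma(mp.mpf(alpha) * k + 1),
                             [0, mp.inf]))


class TestMittagLeffler:
    @pytest.mark.parametrize("alpha", [0.5, 0.86, 0.97, 1.0, 2.0])
    def test_value_at_zero_is_one(self, alpha):
        assert mittag_leffler(alpha, 0.0) == 1.0

    def test_order_one_is_exp(self):
        z = np.linspace(-5, 5, 101)
        vals = np.array([mittag_leffler(1.0, zi) for zi in z])
        assert np.max(np.abs(vals - np.exp(z))) < 1e-10

    def test_order_two_is_cosh(self):
        z = np.linspace(0, 3, 31)
        vals = np.array([mittag_leffler(2.0, zi**2) for zi in z])
        assert np.max(np.abs(vals - np.cosh(z))) < 1e-8

    def test_order_half_erfc_identity(self):
        # E_{1/2}(z) = exp(z^2) * erfc(-z)
        expected = math.e * math.erfc(-1.0)  # = 5.008980080762283
        assert mittag_leffler(0.5, 1.0) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("alpha,z", [(0.5, -31.0), (0.9, -50.0), (0.98, -300.0)])
    def test_large_negative_argument_asymptotic(self, alpha, z):
        """The algebraic tail used beyond the series envelope is accurate."""
        if alpha == 0.5:
            with mp.workdps(50):
                ref = float(mp.exp(mp.mpf(z) ** 2) * mp.erfc(-mp.mpf(z)))
        else:
            with mp.workdps(1200):
                ref = float(sum(mp.mpf(z) ** k / mp.gamma(mp.mpf(alpha) * k + 1)
                                for k in range(3000)))
        assert mittag_leffler(alpha, z) == pytest.approx(ref, rel=1e-8)

    def test_moderate_arguments_match_oracle(self):
        for alpha in (0.86, 0.95, 0.98):
            for z in (-10.0, -1.0, 0.5, 5.0, 25.0):
                # alternating-series cancellation at negative z limits the
                # attainable double-precision accuracy to ~1e-8 relative
                tol = 1e-10 if z > 0 else 1e-6
                assert mittag_leffler(alpha, z) == pytest.approx(
                    ml_reference(alpha, z), rel=tol
                )

    def test_out_of_envelope_raises(self):
        with pytest.raises(MittagLefflerRangeError):
            mittag_leffler(0.9, 1000.0)
        with pytest.raises(MittagLefflerRangeError):
            mittag_leffler(0.1, 5.0)

    def test_invalid_inputs(self):
        with pytest.raises(FractionalOrderError):
            mittag_leffler(-0.5, 1.0)
        with pytest.raises(ValueError):
            mittag_leffler(0.9, 1.0, tol=0.0)


class TestRiemannLiouvilleIntegral:
    def test_order_one_of_constant(self):
        t = np.linspace(0, 3, 301)
        assert rl_integral(np.ones_like(t), 1.0, t) == pytest.approx(3.0, rel=1e-12)

    def test_order_one_of_identity(self):
        t = np.linspace(0, 2, 201)
        assert rl_integral(t, 1.0, t) == pytest.approx(2.0, rel=1e-10)

    def test_half_order_of_constant_closed_form(self):
        # I^alpha 1 = t^alpha / Gamma(alpha+1); at alpha=1/2, t=1: 1/Gamma(1.5)
        t = np.linspace(0, 1, 201)
        expected = 1.0 / math.gamma(1.5)  # 1.1283791670955126
        assert rl_integral(np.ones_like(t), 0.5, t) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.8])
    def test_refinement_halves_error(self, alpha):
        # product trapezoid is exact on linear integrands, so probe with
        # t^2: I^alpha t^2 = 2 t^(alpha+2) / Gamma(alpha+3)
        exact = 2.0 / math.gamma(alpha + 3.0)
        errs = []
        for n in (50, 100, 200):
            t = np.linspace(0, 1, n + 1)
            errs.append(abs(rl_integral(t**2, alpha, t) - exact))
        assert errs[1] <= errs[0] / 2 and errs[2] <= errs[1] / 2

    def test_domain_checks(self):
        t = np.linspace(1, 2, 11)  # does not start at 0
        with pytest.raises(ValueError):
            rl_integral(np.ones_like(t), 0.5, t)


class TestCaputoDerivative:
    def test_constant_has_zero_derivative(self):
        t = np.linspace(0, 4, 101)
        d = caputo_derivative(np.full_like(t, 7.0), 0.6, t)
        assert np.all(d == 0.0)

    def test_identity_function_closed_form(self):
        # D^alpha t = t^(1-alpha) / Gamma(2-alpha); at alpha=1/2, t=1
        t = np.linspace(0, 1, 401)
        d = caputo_derivative(t, 0.5, t)
        assert d[-1] == pytest.approx(1.0 / math.gamma(1.5), rel=1e-6)

    def test_near_integer_order_approaches_classical_derivative(self):
        t = np.linspace(0, 1, 401)
        d = caputo_derivative(t, 0.999, t)
        assert d[-1] == pytest.approx(1.0, rel=5e-3)

    def test_rejects_bad_grids_and_orders(self):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(ValueError):
            caputo_derivative(t, 0.5, t)
        u = np.linspace(0, 1, 11)
        with pytest.raises(FractionalOrderError):
            caputo_derivative(u, 1.0, u)


class TestCaputoSolver:
    def test_classical_exponential(self):
        t = np.round(np.arange(0, 10.001, 0.01), 10)
        traj = solve_caputo_ivp(lambda _t, v: 0.046 * v, 1.0, 1.0, t)
        assert traj.volumes[-1] == pytest.approx(math.exp(0.46), rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.86, 0.95, 0.97])
    def test_linear_rhs_matches_mittag_leffler(self, alpha, day_grid_fine):
        a = 0.109
        traj = solve_caputo_ivp(lambda _t, v: a * v, alpha, 1.0, day_grid_fine)
        exact = np.array(
            [mittag_leffler(alpha, a * t**alpha) for t in day_grid_fine]
        )
        rel = np.max(np.abs(traj.volumes - exact) / exact)
        assert rel < 1e-3

    def test_alpha_one_matches_adaptive_reference(self, day_grid_fine):
        rhs = lambda _t, v: 0.0735 * v * (1 - (v / 2.81) ** 3.35)
        traj = solve_caputo_ivp(rhs, 1.0, 0.5, day_grid_fine)
        ref = solve_ivp(rhs, (0, 18), [0.5], t_eval=day_grid_fine,
                        rtol=1e-10, atol=1e-12)
        rel = np.max(np.abs(traj.volumes - ref.y[0]) / np.abs(ref.y[0]))
        assert rel < 1e-4

    def test_equilibrium_is_preserved_at_any_order(self, day_grid_coarse):
        # logistic started at its carrying capacity stays there
        k = 2.81
        rhs = lambda _t, v: 0.0735 * v * (1 - (v / k) ** 3.35)
        for alpha in (0.8, 1.0):
            traj = solve_caputo_ivp(rhs, alpha, k, day_grid_coarse)
            assert np.max(np.abs(traj.volumes - k)) < 1e-9

    def test_blowup_raises_with_last_valid_time(self):
        t = np.round(np.arange(0, 2.001, 0.01), 10)
        with pytest.raises(SolverDivergenceError) as err:
            solve_caputo_ivp(lambda _t, v: v * v, 1.0, 5.0, t)
        assert 0.0 <= err.value.last_valid_time < 2.0

    def test_order_outside_unit_interval_rejected(self, day_grid_coarse):
        with pytest.raises(FractionalOrderError):
            solve_caputo_ivp(lambda _t, v: v, 1.5, 1.0, day_grid_coarse)


class TestTrajectory:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0, 0.5]), volumes=np.zeros(3))
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0]), volumes=np.array([1.0, np.inf]))

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(step_h=-0.1)
        with pytest.raises(ValueError):
            SolverConfig(corrector_iters=0)
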