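"""Existence, uniqueness and stability diagnostics for the growth models.

The fractional growth equations can be recast, through the
Caputo-Fabrizio operator with normalization constant M(alpha), as the
fixed-point problem

    v(t) = v(0) + phi(alpha) F(t, v(t)) + psi(alpha) int_0^t F(x, v(x)) dx,

    phi(alpha) = (2 - 2 alpha) / (M(alpha) (2 - alpha)),
    psi(alpha) = 2 alpha / ((2 - alpha) M(alpha)).

With theta a Lipschitz constant of the growth law F on the volume range
of interest, Picard iteration converges — i.e. a solution exists — when
``(phi + psi * c) * theta < 1`` for some constant c, and the solution is
unique on [0, t] when ``1 - (phi + psi * t) * theta > 0``.  This module
evaluates those conditions numerically; M(alpha) defaults to 1, the
usual Caputo-Fabrizio normalization.

For the linear (exponential) law the solution envelope is the
Mittag-Leffler function, and stability is classified in the
Mittag-Leffler sense by evaluating the solution at widely spaced times.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .fracnum import mittag_leffler, validate_order
from .growth_models import GrowthModelSpec, ModelKind

__all__ = [
    "StabilityClass",
    "WellPosednessReport",
    "phi_psi",
    "lipschitz_theta",
    "existence_condition_value",
    "existence_check",
    "uniqueness_check",
    "ml_stability_report",
    "wellposedness_report",
]

#: Default volume range for Lipschitz estimation: zero up to the
#: censoring threshold expressed in model units (2000 mm^3 / 100).
DEFAULT_V_RANGE = (0.0, 20.0)


class StabilityClass(str, enum.Enum):
    BOUNDED_CONVERGENT = "bounded_convergent"
    UNBOUNDED_GROWTH = "unbounded_growth"
    DECAYING = "decaying"


def phi_psi(alpha: float, M_alpha: float = 1.0) -> tuple[float, float]:
    """Coefficients of the fixed-point form; phi vanishes at alpha = 1."""
    alpha = validate_order(alpha)
    if M_alpha <= 0:
        raise ValueError("M_alpha must be positive")
    phi = (2.0 - 2.0 * alpha) / (M_alpha * (2.0 - alpha))
    psi = 2.0 * alpha / ((2.0 - alpha) * M_alpha)
    return phi, psi


def lipschitz_theta(
    model: GrowthModelSpec,
    v_range: tuple[float, float] = DEFAULT_V_RANGE,
    n_grid: int = 2001,
) -> float:
    """Lipschitz constant of the growth law on ``v_range``.

    For the exponential law the constant is exactly the kinetic
    parameter a.  For the other laws the supremum of |df/dv| is taken
    over a dense grid on the range; singular endpoints (v + c <= 0 for
    Gompertz, v = 0 where a power-law exponent is below 1) are excluded
    by nudging the grid inward.
    """
    lo, hi = float(v_range[0]), float(v_range[1])
    if not lo < hi:
        raise ValueError("v_range must be a non-degenerate interval")
    if model.kind is ModelKind.EXPONENTIAL:
        return model.params["a"]
    if model.kind is ModelKind.GOMPERTZ and lo + model.params["c"] <= 0:
        raise ValueError("gompertz Lipschitz range requires v + c > 0")
    eps = 1e-9 * max(1.0, hi)
    needs_pos = model.kind is ModelKind.BP_PARTICULAR or (
        model.kind is ModelKind.BP_GENERAL
        and min(model.params["a"], model.params["b"]) < 1.0
    )
    if needs_pos and lo <= 0.0:
        lo = eps
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([abs(model.rhs_dv(float(v))) for v in grid])
    return float(np.max(vals))


def existence_condition_value(
    alpha: float, theta: float, c_bound: float, M_alpha: float = 1.0
) -> float:
    """The contraction product ``(phi + psi * c) * theta``."""
    if theta < 0 or c_bound < 0:
        raise ValueError("theta and c_bound must be non-negative")
    phi, psi = phi_psi(alpha, M_alpha)
    return (phi + psi * c_bound) * theta


def existence_check(
    alpha: float, theta: float, c_bound: float, M_alpha: float = 1.0
) -> bool:
    """Existence holds when ``(phi + psi * c) * theta < 1`` (strict)."""
    return existence_condition_value(alpha, theta, c_bound, M_alpha) < 1.0


def uniqueness_check(
    alpha: float, theta: float, t_bound: float, M_alpha: float = 1.0
) -> bool:
    """Uniqueness on [0, t] holds when ``1 - (phi + psi * t) * theta > 0``."""
    return 1.0 - existence_condition_value(alpha, theta, t_bound, M_alpha) > 0.0


_ENVELOPE_TIMES = (10.0, 100.0, 1000.0)


def _log_envelope(alpha: float, a: float, t: float) -> float:
    """log E_alpha(a t^alpha), with the exponential asymptotic for large
    positive arguments where the series would overflow."""
    z = a * t**alpha
    if z > 30.0:
        # E_alpha(z) ~ (1/alpha) exp(z^(1/alpha)) for z -> +inf
        return z ** (1.0 / alpha) - math.log(alpha)
    val = mittag_leffler(alpha, z)
    return math.log(val) if val > 0 else -math.inf


@dataclass(frozen=True)
class MLStabilityReport:
    alpha: float
    a: float
    classification: StabilityClass
    envelope_ratios: tuple  # v(t)/v(0) (or its log for growth) at 10, 100, 1000 days


def ml_stability_report(alpha: float, a: float) -> MLStabilityReport:
    """Mittag-Leffler stability of D^alpha v = a v.

    The solution envelope v(t)/v(0) = E_alpha(a t^alpha) is evaluated at
    t in {10, 100, 1000} days.  a < 0 gives algebraic decay (the
    Mittag-Leffler function of a negative argument), a = 0 a constant
    solution, a > 0 monotone unbounded growth.
    """
    alpha = validate_order(alpha)
    if a == 0.0:
        return MLStabilityReport(alpha, a, StabilityClass.BOUNDED_CONVERGENT,
                                 (1.0, 1.0, 1.0))
    if a < 0.0:
        ratios = tuple(mittag_leffler(alpha, a * t**alpha) for t in _ENVELOPE_TIMES)
        decaying = all(np.diff(ratios) < 0) or ratios[-1] < ratios[0]
        cls = StabilityClass.DECAYING if decaying else StabilityClass.BOUNDED_CONVERGENT
        return MLStabilityReport(alpha, a, cls, ratios)
    logs = tuple(_log_envelope(alpha, a, t) for t in _ENVELOPE_TIMES)
    growing = logs[0] < logs[1] < logs[2]
    cls = StabilityClass.UNBOUNDED_GROWTH if growing else StabilityClass.BOUNDED_CONVERGENT
    return MLStabilityReport(alpha, a, cls, logs)


@dataclass(frozen=True)
class WellPosednessReport:
    alpha: float
    M_alpha: float
    phi: float
    psi: float
    theta: float
    c_bound: float
    t_bound: float
    existence_value: float
    uniqueness_value: float
    existence_ok: bool
    uniqueness_ok: bool


def wellposedness_report(
    model: GrowthModelSpec,
    alpha: float,
    v_range: tuple[float, float] = DEFAULT_V_RANGE,
    c_bound: float = 1.0,
    t_bound: float = 18.0,
    M_alpha: float = 1.0,
) -> WellPosednessReport:
    """Full diagnostic for one model at one fractional order.

    ``c_bound`` and ``t_bound`` are the free constants of the two
    conditions; the defaults (1 and the 18-day horizon) are surfaced
    choices, not derived quantities.
    """
    phi, psi = phi_psi(alpha, M_alpha)
    theta = lipschitz_theta(model, v_range)
    ev = existence_condition_value(alpha, theta, c_bound, M_alpha)
    uv = 1.0 - existence_condition_value(alpha, theta, t_bound, M_alpha)
    return WellPosednessReport(
        alpha=alpha, M_alpha=M_alpha, phi=phi, psi=psi, theta=theta,
        c_bound=c_bound, t_bound=t_bound,
        existence_value=ev, uniqueness_value=uv,
        existence_ok=ev < 1.0, uniqueness_ok=uv > 0.0,
    )
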