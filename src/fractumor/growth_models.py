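"""Tumor growth laws and their fractional-order generalizations.

Five deterministic growth laws for tumor volume v(t), each used both at
integer order (dv/dt = f(v)) and as a Caputo fractional equation
(D^alpha v = f(v), 0 < alpha <= 1):

* exponential:     f(v) = a v
* logistic:        f(v) = a v (1 - (v/k)^b)
* gompertz:        f(v) = a v ln(b / (v + c))        (canonical form)
                   f(v) = a   ln(b / (v + c))        (alternate form)
* bp_general:      f(v) = p v^a - q v^b,  a != b     (Bertalanffy-Putter)
* bp_particular:   f(v) = p v^a - ln(v) q v^a        (a == b limit)

All parameters are positive constants; volumes are in "model volume
units" (1 unit = 100 mm^3 by this package's convention, see the methods
note).  Both Gompertz variants circulate in the literature — with and
without the v(t) factor — so the form is an explicit argument rather
than a silent choice.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .fracnum import SolverConfig, Trajectory, mittag_leffler, solve_caputo_ivp, validate_order

__all__ = [
    "ModelKind",
    "GompertzForm",
    "GrowthModelSpec",
    "rhs_exponential",
    "rhs_logistic",
    "rhs_gompertz",
    "rhs_bertalanffy",
    "analytic_fractional_exponential",
    "analytic_integer_solution",
    "simulate_model",
    "PARAM_NAMES",
]


class ModelKind(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    BP_GENERAL = "bp_general"
    BP_PARTICULAR = "bp_particular"


class GompertzForm(str, enum.Enum):
    #: f(v) = a * v * ln(b / (v + c))
    WITH_V_FACTOR = "with_v_factor"
    #: f(v) = a * ln(b / (v + c))
    WITHOUT_V_FACTOR = "without_v_factor"


PARAM_NAMES: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.EXPONENTIAL: ("a",),
    ModelKind.LOGISTIC: ("a", "k", "b"),
    ModelKind.GOMPERTZ: ("a", "b", "c"),
    ModelKind.BP_GENERAL: ("p", "q", "a", "b"),
    ModelKind.BP_PARTICULAR: ("p", "q", "a"),
}

_BP_EXPONENT_TOL = 1e-6


def rhs_exponential(v: float, a: float) -> float:
    """dv/dt = a v; a is the growth exponent (kinetic parameter)."""
    if v < 0:
        raise ValueError("volume must be non-negative")
    if a <= 0:
        raise ValueError("a must be positive")
    return a * v


def rhs_logistic(v: float, a: float, k: float, b: float) -> float:
    """dv/dt = a v (1 - (v/k)^b); k is the carrying capacity."""
    if v < 0:
        raise ValueError("volume must be non-negative")
    if min(a, k, b) <= 0:
        raise ValueError("a, k, b must be positive")
    if v == 0.0:
        return 0.0
    return a * v * (1.0 - (v / k) ** b)


def rhs_gompertz(
    v: float, a: float, b: float, c: float,
    form: GompertzForm = GompertzForm.WITH_V_FACTOR,
) -> float:
    """Gompertz growth rate; c offsets the minimum carrying capacity.

    The canonical form a*v*ln(b/(v+c)) has equilibria at v = 0 and
    v = b - c; the alternate form a*ln(b/(v+c)) only at v = b - c.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if v + c <= 0:
        raise ValueError("gompertz rhs requires v + c > 0")
    log_term = math.log(b / (v + c))
    if form is GompertzForm.WITH_V_FACTOR:
        return a * v * log_term
    return a * log_term


def rhs_bertalanffy(v: float, spec: "GrowthModelSpec") -> float:
    """Bertalanffy-Putter growth rate (general or particular branch).

    General (a != b): p v^a - q v^b; p is intrinsic growth, q the
    antiangiogenic decline factor.  Particular (shared exponent):
    p v^a - ln(v) q v^a, requiring v > 0.
    """
    p = spec.params["p"]
    q = spec.params["q"]
    if spec.kind is ModelKind.BP_GENERAL:
        if v < 0:
            raise ValueError("volume must be non-negative")
        return p * v ** spec.params["a"] - q * v ** spec.params["b"]
    if spec.kind is ModelKind.BP_PARTICULAR:
        if v <= 0:
            raise ValueError("particular Bertalanffy-Putter form requires v > 0")
        va = v ** spec.params["a"]
        return p * va - math.log(v) * q * va
    raise ValueError(f"not a Bertalanffy-Putter spec: {spec.kind}")


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth law plus its positive parameter record."""

    kind: ModelKind
    params: dict
    gompertz_form: GompertzForm = GompertzForm.WITH_V_FACTOR

    def __post_init__(self):
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "gompertz_form", GompertzForm(self.gompertz_form))
        expected = PARAM_NAMES[kind]
        got = tuple(self.params)
        if set(got) != set(expected):
            raise ValueError(
                f"{kind.value} expects parameters {expected}, got {got}"
            )
        params = {name: float(self.params[name]) for name in expected}
        for name, value in params.items():
            if value <= 0 or not math.isfinite(value):
                raise ValueError(
                    f"{kind.value} parameter {name} must be a positive finite "
                    f"number, got {value!r}"
                )
        if kind is ModelKind.BP_GENERAL and abs(params["a"] - params["b"]) < _BP_EXPONENT_TOL:
            raise ValueError(
                "bp_general requires distinct exponents a != b; "
                "use bp_particular for the shared-exponent branch"
            )
        object.__setattr__(self, "params", params)

    def rhs(self, v: float) -> float:
        """Growth rate f(v) for this law (time does not enter)."""
        p = self.params
        if self.kind is ModelKind.EXPONENTIAL:
            return rhs_exponential(v, p["a"])
        if self.kind is ModelKind.LOGISTIC:
            return rhs_logistic(v, p["a"], p["k"], p["b"])
        if self.kind is ModelKind.GOMPERTZ:
            return rhs_gompertz(v, p["a"], p["b"], p["c"], self.gompertz_form)
        return rhs_bertalanffy(v, self)

    def rhs_dv(self, v: float) -> float:
        """Analytic derivative d f / d v, used by Lipschitz diagnostics."""
        p = self.params
        if self.kind is ModelKind.EXPONENTIAL:
            return p["a"]
        if self.kind is ModelKind.LOGISTIC:
            if v == 0.0:
                return p["a"]
            return p["a"] * (1.0 - (p["b"] + 1.0) * (v / p["k"]) ** p["b"])
        if self.kind is ModelKind.GOMPERTZ:
            if v + p["c"] <= 0:
                raise ValueError("gompertz derivative requires v + c > 0")
            if self.gompertz_form is GompertzForm.WITH_V_FACTOR:
                return p["a"] * (math.log(p["b"] / (v + p["c"])) - v / (v + p["c"]))
            return -p["a"] / (v + p["c"])
        if self.kind is ModelKind.BP_GENERAL:
            if v == 0.0:
                v = 0.0  # derivative handled by caller's grid choice
            return (
                p["p"] * p["a"] * v ** (p["a"] - 1.0)
                - p["q"] * p["b"] * v ** (p["b"] - 1.0)
            )
        # particular: d/dv [p v^a - q ln(v) v^a]
        if v <= 0:
            raise ValueError("particular form derivative requires v > 0")
        va1 = v ** (p["a"] - 1.0)
        return va1 * (p["p"] * p["a"] - p["q"] * (1.0 + p["a"] * math.log(v)))


def analytic_fractional_exponential(
    t: float, a: float, alpha: float, v0: float
) -> float:
    """Closed-form solution of D^alpha v = a v: v(t) = v0 E_alpha(a t^alpha).

    Reduces to v0 * exp(a t) at alpha = 1 and is monotone increasing in t
    for a > 0.
    """
    alpha = validate_order(alpha)
    if t < 0:
        raise ValueError("t must be non-negative")
    return v0 * mittag_leffler(alpha, a * t**alpha)


def analytic_integer_solution(
    kind: ModelKind, params: dict, v0: float, t_grid: np.ndarray
) -> Trajectory:
    """Textbook closed forms at integer order, for use as solver oracles.

    Supports the exponential law, the logistic law with b = 1, and the
    canonical Gompertz law with c = 0.  Raises ``NotImplementedError``
    for combinations without a closed form.
    """
    kind = ModelKind(kind)
    t = np.asarray(t_grid, dtype=float)
    if kind is ModelKind.EXPONENTIAL:
        v = v0 * np.exp(params["a"] * t)
    elif kind is ModelKind.LOGISTIC and abs(params.get("b", np.nan) - 1.0) < 1e-12:
        k, a = params["k"], params["a"]
        v = k * v0 * np.exp(a * t) / (k + v0 * (np.exp(a * t) - 1.0))
    elif kind is ModelKind.GOMPERTZ and params.get("c", np.nan) == 0.0 and v0 > 0:
        a, b = params["a"], params["b"]
        v = b * (v0 / b) ** np.exp(-a * t)
    else:
        raise NotImplementedError(
            f"no closed form implemented for {kind.value} with {params}"
        )
    return Trajectory(times=t, volumes=v)


def simulate_model(
    spec: GrowthModelSpec,
    alpha: float,
    v0: float,
    t_grid: np.ndarray,
    config: SolverConfig | None = None,
) -> Trajectory:
    """Solve D^alpha v = f(v) for a growth law on ``t_grid``."""
    return solve_caputo_ivp(
        lambda _t, v: spec.rhs(v), alpha, v0, t_grid, config=config
    )
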