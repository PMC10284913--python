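"""Reference fitted parameter sets for murine tumor-volume data.

Fitted kinetic parameters, fractional orders and mean squared errors for
the five growth laws on a treated and an untreated murine tumor arm
(orthotopic transplant, 18-day observation window).  These values define
the realistic parameter scale for this package: the synthetic-data
generator, the test fixtures and the worked examples all draw from them.

Volumes are in model volume units (1 unit = 100 mm^3); rates carry
implied units day^-alpha.  The Gompertz rows use the form without the
v(t) factor, i.e. dv/dt = a ln(b/(v+c)).
"""

from __future__ import annotations

from .growth_models import GompertzForm, GrowthModelSpec, ModelKind

__all__ = [
    "REFERENCE_PARAMS",
    "REFERENCE_ALPHA",
    "REFERENCE_MSE",
    "reference_spec",
]

#: Fitted integer-order parameters per (model kind, arm).
REFERENCE_PARAMS: dict[tuple[ModelKind, str], dict] = {
    (ModelKind.EXPONENTIAL, "treated"): {"a": 0.046},
    (ModelKind.EXPONENTIAL, "untreated"): {"a": 0.109},
    (ModelKind.LOGISTIC, "treated"): {"a": 0.0735, "k": 2.81, "b": 3.35},
    (ModelKind.LOGISTIC, "untreated"): {"a": 0.565, "k": 35.2, "b": 0.134},
    (ModelKind.GOMPERTZ, "treated"): {"a": 0.204, "b": 8.81, "c": 5.04},
    (ModelKind.GOMPERTZ, "untreated"): {"a": 0.106, "b": 26.09, "c": 2.24},
    (ModelKind.BP_GENERAL, "treated"): {"p": 0.168, "q": 0.1, "a": 2.18, "b": 2.66},
    (ModelKind.BP_GENERAL, "untreated"): {"p": 0.894, "q": 0.741, "a": 1.38, "b": 1.44},
    (ModelKind.BP_PARTICULAR, "treated"): {"p": 0.064, "q": 0.063, "a": 2.41},
    (ModelKind.BP_PARTICULAR, "untreated"): {"p": 0.203, "q": 0.011, "a": 0.74},
}

#: Best fractional order per (model kind, arm), parameters held fixed.
REFERENCE_ALPHA: dict[tuple[ModelKind, str], float] = {
    (ModelKind.EXPONENTIAL, "treated"): 0.97,
    (ModelKind.EXPONENTIAL, "untreated"): 0.98,
    (ModelKind.LOGISTIC, "treated"): 0.94,
    (ModelKind.LOGISTIC, "untreated"): 0.88,
    (ModelKind.GOMPERTZ, "treated"): 0.95,
    (ModelKind.GOMPERTZ, "untreated"): 0.86,
    (ModelKind.BP_GENERAL, "treated"): 0.96,
    (ModelKind.BP_GENERAL, "untreated"): 0.96,
    (ModelKind.BP_PARTICULAR, "treated"): 0.96,
    (ModelKind.BP_PARTICULAR, "untreated"): 0.95,
}

#: Reported MSE per (model kind, arm, order) with order in {"integer", "fractional"}.
REFERENCE_MSE: dict[tuple[ModelKind, str, str], float] = {
    (ModelKind.EXPONENTIAL, "treated", "integer"): 0.0457,
    (ModelKind.EXPONENTIAL, "treated", "fractional"): 0.022,
    (ModelKind.EXPONENTIAL, "untreated", "integer"): 2.74,
    (ModelKind.EXPONENTIAL, "untreated", "fractional"): 0.94,
    (ModelKind.LOGISTIC, "treated", "integer"): 0.0236,
    (ModelKind.LOGISTIC, "treated", "fractional"): 0.0156,
    (ModelKind.LOGISTIC, "untreated", "integer"): 2.506,
    (ModelKind.LOGISTIC, "untreated", "fractional"): 0.394,
    (ModelKind.GOMPERTZ, "treated", "integer"): 0.0218,
    (ModelKind.GOMPERTZ, "treated", "fractional"): 0.0146,
    (ModelKind.GOMPERTZ, "untreated", "integer"): 2.4066,
    (ModelKind.GOMPERTZ, "untreated", "fractional"): 0.3824,
    (ModelKind.BP_GENERAL, "treated", "integer"): 0.0216,
    (ModelKind.BP_GENERAL, "treated", "fractional"): 0.0150,
    (ModelKind.BP_GENERAL, "untreated", "integer"): 0.8557,
    (ModelKind.BP_GENERAL, "untreated", "fractional"): 0.2243,
    (ModelKind.BP_PARTICULAR, "treated", "integer"): 0.0215,
    (ModelKind.BP_PARTICULAR, "treated", "fractional"): 0.0149,
    (ModelKind.BP_PARTICULAR, "untreated", "integer"): 1.0682,
    (ModelKind.BP_PARTICULAR, "untreated", "fractional"): 0.2273,
}


def reference_spec(
    kind: ModelKind | str,
    arm: str,
    gompertz_form: GompertzForm = GompertzForm.WITH_V_FACTOR,
) -> GrowthModelSpec:
    """Build a :class:`GrowthModelSpec` from the reference table."""
    kind = ModelKind(kind)
    params = REFERENCE_PARAMS[(kind, arm)]
    return GrowthModelSpec(kind=kind, params=dict(params), gompertz_form=gompertz_form)
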