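"""Synthetic murine tumor-volume experiments.

Generates treated and untreated measurement sets with the protocol
structure of an orthotopic mouse tumor study: an 18-day horizon,
measurements every 2-3 days, a treated arm receiving drug when the
recorded volume first reaches 200 mm^3 with at least 10 days between
doses (8 mg/kg, recorded but not mechanistically modeled), and censoring
once a recorded volume reaches 2000 mm^3.

The underlying dynamics come from the fractional growth laws in
:mod:`fractumor.growth_models`.  Treatment is represented by an
instantaneous log-kill: at each dose time the volume drops by a fixed
fraction kappa and the Caputo solver is restarted from the post-kill
volume (the memory of the pre-dose trajectory is deliberately reset at
the intervention).  Measurement noise is multiplicative lognormal,
calibrated to mean 1 so noisy and noise-free volumes agree in
expectation.

The generator works internally in model volume units (1 unit = 100 mm^3)
and reports measurements in mm^3, matching the CSV convention of
:mod:`fractumor.cli_io`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .fracnum import SolverConfig, Trajectory
from .growth_models import GompertzForm, GrowthModelSpec, ModelKind, simulate_model

__all__ = [
    "MM3_PER_MODEL_UNIT",
    "TreatmentProtocol",
    "TreatmentEffect",
    "NoiseModel",
    "Experiment",
    "simulate_experiment",
    "make_fixture_pair",
    "DEFAULT_FIXTURE_SPEC",
]

#: Declared unit conversion: 1 model volume unit = 100 mm^3.
MM3_PER_MODEL_UNIT = 100.0


@dataclass(frozen=True)
class TreatmentProtocol:
    """Clinician dosing protocol applied at observation times."""

    dose_threshold_mm3: float = 200.0
    min_dose_interval_days: float = 10.0
    dose_mg_per_kg: float = 8.0       # recorded, not mechanistically used
    stop_threshold_mm3: float = 2000.0
    horizon_days: float = 18.0
    #: alternating cadence in days; 3,2 makes the final observation land
    #: exactly on the 18-day horizon (0, 3, 5, 8, 10, 13, 15, 18)
    sampling_intervals: tuple = (3, 2)

    def __post_init__(self):
        if not (0 < self.dose_threshold_mm3 < self.stop_threshold_mm3):
            raise ValueError("need 0 < dose threshold < stop threshold")
        if self.min_dose_interval_days > self.horizon_days:
            raise ValueError("min dose interval must fit within the horizon")
        if not all(int(d) == d and d in (2, 3) for d in self.sampling_intervals):
            raise ValueError("sampling cadence must use 2- or 3-day intervals")

    def sample_times(self) -> np.ndarray:
        """Observation days: 0, then alternating 2/3-day steps up to the horizon."""
        times = [0.0]
        i = 0
        while True:
            nxt = times[-1] + self.sampling_intervals[i % len(self.sampling_intervals)]
            if nxt > self.horizon_days:
                break
            times.append(float(nxt))
            i += 1
        return np.asarray(times)


@dataclass(frozen=True)
class TreatmentEffect:
    """Instantaneous log-kill surrogate: post-dose = (1 - kappa) * pre-dose."""

    kill_fraction: float = 0.4

    def __post_init__(self):
        if not (0.0 <= self.kill_fraction < 1.0):
            raise ValueError("kill_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise with unit mean."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sigma <= 0.5):
            raise ValueError("sigma must lie in [0, 0.5]")

    def apply(self, volumes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0.0:
            return np.array(volumes, dtype=float)
        eps = rng.standard_normal(len(volumes))
        # exp(sigma*eps - sigma^2/2) has expectation exactly 1
        return volumes * np.exp(self.sigma * eps - 0.5 * self.sigma**2)


@dataclass(frozen=True)
class Experiment:
    """One simulated arm: sampled measurements plus the dose log."""

    times_days: np.ndarray
    volumes_mm3: np.ndarray           # noisy recorded values
    true_volumes_mm3: np.ndarray      # noise-free values at sample times
    dose_times_days: tuple
    censored: bool


def _solve_piecewise(spec, alpha, v0_units, sample_times, protocol, effect,
                     noise, rng, step_h):
    """Dense piecewise solve with solver restarts at dose events.

    Returns (true, recorded) volumes in model units at sample times plus
    the dose log.  The protocol is observation-driven: the dose trigger
    is evaluated against the *recorded* (noisy) measurement at each
    observation time, while the log-kill acts on the true tumor state.
    """
    dose_times = []
    true_v = np.empty(sample_times.size)
    rec_v = np.empty(sample_times.size)
    true_v[0] = v0_units
    noise_factors = (
        np.exp(noise.sigma * rng.standard_normal(sample_times.size)
               - 0.5 * noise.sigma**2)
        if noise.sigma > 0.0
        else np.ones(sample_times.size)
    )
    rec_v[0] = true_v[0] * noise_factors[0]
    seg_start_t = 0.0
    seg_v0 = v0_units
    last_dose = -math.inf

    treat = protocol is not None and effect is not None
    thr_units = (protocol.dose_threshold_mm3 / MM3_PER_MODEL_UNIT) if treat else math.inf

    def maybe_dose(i: int) -> None:
        nonlocal seg_start_t, seg_v0, last_dose
        t_i = sample_times[i]
        if rec_v[i] >= thr_units and (t_i - last_dose) >= protocol.min_dose_interval_days:
            dose_times.append(float(t_i))
            last_dose = t_i
            # a zero-effect dose does not perturb the dynamics, so the
            # solver (and its Caputo memory) is only restarted when the
            # log-kill actually changes the state
            if effect.kill_fraction > 0.0:
                seg_start_t = t_i
                seg_v0 = (1.0 - effect.kill_fraction) * true_v[i]

    if treat:
        maybe_dose(0)
    for i in range(1, sample_times.size):
        t_i = sample_times[i]
        # uniform local grid from the last restart to this observation
        n = max(1, int(round((t_i - seg_start_t) / step_h)))
        local_t = np.linspace(0.0, t_i - seg_start_t, n + 1)
        traj = simulate_model(spec, alpha, seg_v0, local_t,
                              config=SolverConfig(step_h=local_t[1] - local_t[0]))
        true_v[i] = float(traj.volumes[-1])
        rec_v[i] = true_v[i] * noise_factors[i]
        if treat:
            maybe_dose(i)
    return true_v, rec_v, tuple(dose_times)


def simulate_experiment(
    model: GrowthModelSpec,
    alpha: float,
    protocol: TreatmentProtocol | None,
    effect: TreatmentEffect | None,
    noise: NoiseModel,
    v0_mm3: float,
    step_h: float = 0.01,
    horizon_days: float | None = None,
) -> Experiment:
    """Simulate one experimental arm and sample it like the bench protocol.

    With ``protocol=None`` the arm is untreated (pure growth).  Censoring
    applies in both arms: the record is truncated at the first *recorded*
    (noisy) sample at or above the stop threshold, which is retained as
    the terminal sample.
    """
    if v0_mm3 <= 0:
        raise ValueError("v0_mm3 must be positive")
    proto_for_times = protocol if protocol is not None else TreatmentProtocol()
    if horizon_days is not None:
        proto_for_times = TreatmentProtocol(
            dose_threshold_mm3=proto_for_times.dose_threshold_mm3,
            min_dose_interval_days=min(proto_for_times.min_dose_interval_days, horizon_days),
            stop_threshold_mm3=proto_for_times.stop_threshold_mm3,
            horizon_days=horizon_days,
            sampling_intervals=proto_for_times.sampling_intervals,
        )
    sample_times = proto_for_times.sample_times()
    v0_units = v0_mm3 / MM3_PER_MODEL_UNIT

    rng = np.random.default_rng(noise.seed)
    true_units, rec_units, dose_times = _solve_piecewise(
        model, alpha, v0_units, sample_times, protocol, effect, noise, rng, step_h
    )
    true_mm3 = true_units * MM3_PER_MODEL_UNIT
    noisy_mm3 = rec_units * MM3_PER_MODEL_UNIT

    stop = proto_for_times.stop_threshold_mm3
    censored = False
    cut = sample_times.size
    for i, v in enumerate(noisy_mm3):
        if v >= stop:
            cut = i + 1  # keep the terminal censoring sample
            censored = True
            break
    return Experiment(
        times_days=sample_times[:cut],
        volumes_mm3=noisy_mm3[:cut],
        true_volumes_mm3=true_mm3[:cut],
        dose_times_days=tuple(t for t in dose_times if t <= sample_times[cut - 1]),
        censored=censored,
    )


#: Default fixture dynamics: canonical-form Gompertz law at untreated
#: reference scale, mildly fractional order.
DEFAULT_FIXTURE_SPEC = dict(
    kind=ModelKind.GOMPERTZ,
    params={"a": 0.106, "b": 26.09, "c": 2.24},
    alpha=0.9,
    v0_mm3=50.0,
    sigma=0.05,
    kappa=0.4,
)


def _format_csv(times: np.ndarray, volumes: np.ndarray) -> str:
    lines = ["time_days,volume_mm3"]
    for t, v in zip(times, volumes):
        lines.append(f"{t:.6g},{v:.12g}")
    return "\n".join(lines) + "\n"


def make_fixture_pair(seed: int, out_dir, config: dict | None = None):
    """Write a treated/untreated CSV pair plus a ground-truth manifest.

    Output is deterministic in ``seed`` (byte-identical files on repeat
    calls).  The manifest records everything a parameter-recovery test
    needs: model kind, true parameters, true alpha, kappa, sigma, the
    dose times, and the unit conversion.

    Returns the paths (treated_csv, untreated_csv, manifest_json).
    """
    cfg = dict(DEFAULT_FIXTURE_SPEC)
    if config:
        cfg.update(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spec = GrowthModelSpec(kind=cfg["kind"], params=dict(cfg["params"]))
    protocol = TreatmentProtocol()
    effect = TreatmentEffect(kill_fraction=cfg["kappa"])
    # independent substreams for the two arms, both reproducible from seed
    seeds = np.random.SeedSequence(seed).generate_state(2)
    treated = simulate_experiment(
        spec, cfg["alpha"], protocol, effect,
        NoiseModel(sigma=cfg["sigma"], seed=int(seeds[0]) % 2**31),
        cfg["v0_mm3"],
    )
    untreated = simulate_experiment(
        spec, cfg["alpha"], None, None,
        NoiseModel(sigma=cfg["sigma"], seed=int(seeds[1]) % 2**31),
        cfg["v0_mm3"],
    )

    paths = (out_dir / "treated.csv", out_dir / "untreated.csv",
             out_dir / "manifest.json")
    paths[0].write_text(_format_csv(treated.times_days, treated.volumes_mm3),
                        encoding="utf-8", newline="\n")
    paths[1].write_text(_format_csv(untreated.times_days, untreated.volumes_mm3),
                        encoding="utf-8", newline="\n")
    manifest = {
        "model_kind": ModelKind(cfg["kind"]).value,
        "params": dict(cfg["params"]),
        "alpha": cfg["alpha"],
        "v0_mm3": cfg["v0_mm3"],
        "seed": int(seed),
        "sigma": cfg["sigma"],
        "kappa": cfg["kappa"],
        "dose_times_days": list(treated.dose_times_days),
        "mm3_per_model_unit": MM3_PER_MODEL_UNIT,
    }
    paths[2].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8", newline="\n")
    return paths
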