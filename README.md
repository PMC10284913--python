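# fractumor

Fractional-order tumor growth modeling: five classical growth laws, their
Caputo fractional generalizations, and the two-stage procedure that asks
whether a fractional derivative order improves the fit to tumor-volume
time series.

## The problem

Tumor volume measurements v(t) from small-animal experiments are
routinely summarized by deterministic growth laws:

| law | dv/dt | parameters |
|---|---|---|
| exponential | a·v | a |
| logistic | a·v·(1 − (v/k)^b) | a, k, b |
| Gompertz | a·v·ln(b/(v+c)) (or a·ln(b/(v+c))) | a, b, c |
| Bertalanffy–Pütter, general | p·v^a − q·v^b (a ≠ b) | p, q, a, b |
| Bertalanffy–Pütter, particular | p·v^a − ln(v)·q·v^a | p, q, a |

Biological growth carries memory — the state of a tumor reflects its
history, not only its present size. Replacing d/dt with the Caputo
fractional derivative of order α ∈ (0, 1],

    D^α v(t) = (1/Γ(1−α)) ∫₀ᵗ v′(τ) (t−τ)^(−α) dτ,

gives each law one extra degree of freedom with exactly that character:
the right-hand side at time t is weighed against the whole trajectory
history. At α = 1 the classical law is recovered; the linear case
D^α v = a·v has the closed form v(t) = v₀·E_α(a·t^α) with E_α the
Mittag–Leffler function, the fractional generalization of the
exponential.

The identification procedure is deliberately two-staged so the effect of
α is isolated: (1) fit each law's kinetic parameters at α = 1 by
Nelder–Mead minimization of the mean squared error
MSE = (1/n) Σ (yᵢ − ŷᵢ)² on spline-resampled measurements; (2) freeze
those parameters and sweep α over a grid in (0, 1], selecting the
MSE-minimizing order. Because the grid contains α = 1, the fractional
stage can never do worse than the integer fit.

Since the underlying mouse dataset (orthotopic tumor transplants in FVB
mice, 18-day observation, protocol-driven dosing) is not public, the
package includes a synthetic generator that emulates the experiment's
structure: measurements every 2–3 days in mm³, a treated arm dosed when
the recorded volume reaches 200 mm³ with ≥ 10 days between doses
(modeled as an instantaneous log-kill), censoring at 2000 mm³, and
multiplicative lognormal measurement noise.

## What is in the package

- `fractumor.fracnum` — Mittag–Leffler function, Riemann–Liouville
  integral, Caputo derivative (L1 scheme), and an Adams–Bashforth–Moulton
  predictor–corrector solver for Caputo initial-value problems.
- `fractumor.growth_models` — the five laws, parameter validation, and
  analytic solutions used as oracles.
- `fractumor.fitting` — spline resampling, MSE, the two-stage fit, and
  the integer-versus-fractional comparison report.
- `fractumor.synthetic_data` — the protocol-faithful experiment
  generator.
- `fractumor.wellposedness` — numeric existence/uniqueness conditions
  (via the Caputo–Fabrizio fixed-point form) and Mittag–Leffler
  stability classification.
- `fractumor.cli_io` / `fractumor.cli` — CSV/config/report I/O, the
  `fractumor` command-line tool (`simulate`, `fit`, `sweep`, `compare`,
  `report`).
- `analysis/01…05_*.py` — numbered drivers that run the full study on
  synthetic data and write tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_experiments.py
python analysis/04_compare_orders.py
```

prints (seed 1):

```
true dynamics: fractional gompertz (alpha=0.9), params {'a': 0.106, 'b': 26.09, 'c': 2.24}
dose times (days): [8.0, 18.0], log-kill kappa=0.4, noise sigma=0.05
treated: 8 measurements, final volume 577 mm^3 at day 18
untreated: 8 measurements, final volume 694 mm^3 at day 18
...
dataset    model             int MSE  frac MSE  alpha*  ratio %
treated    exponential         2.403     2.403    1.00   100.00
treated    logistic           0.4319    0.4297    0.99    99.50
untreated  logistic           0.2368    0.2365    0.99    99.88
untreated  bp_general        0.06518   0.06518    1.00   100.00
...
```

Reading this: MSEs are in model volume units squared (1 unit = 100 mm³).
The rigid exponential law fits the dosed, non-monotone treated arm
poorly (MSE 2.4) regardless of order; the flexible laws fit well, and
for the logistic and Gompertz laws the order sweep finds a small
interior optimum (α* = 0.99) — the fractional/integer MSE ratio below
100 % quantifies what the extra order bought. When the integer-stage
optimizer has fully compensated the dynamics with its kinetic
parameters, the sweep correctly returns the boundary α* = 1. The
magnitude of the fractional gain depends strongly on how constrained
the integer model is (see `docs/methods.md`).

The library surface mirrors the same steps:

```python
import numpy as np
from fractumor import (GrowthModelSpec, fit_integer, fit_alpha,
                       spline_resample, read_trajectory_csv)

t, v_mm3 = read_trajectory_csv("results/fixtures/untreated.csv")
data = spline_resample(t, v_mm3 / 100.0, grid_step=0.1)
stage1 = fit_integer("gompertz", data, v0=0.01)
stage2, sweep = fit_alpha("gompertz", stage1.model.params, data, v0=0.01)
print(stage1.mse, stage2.mse, stage2.alpha)
```

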