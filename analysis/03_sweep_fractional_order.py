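#!/usr/bin/env python
"""Sweep the fractional order for each fitted law (stage two).

With the integer-stage parameters held fixed, solve the Caputo equation
for every order on the default grid [0.70, 1.00] (step 0.01) and record
the MSE, producing one MSE-versus-alpha curve per (arm, law) pair under
results/sweeps/.  The minimum of each curve is the selected fractional
order; the curve shape shows whether an interior optimum exists.

Run analysis/02_fit_integer_models.py first (or this script refits).
"""

from pathlib import Path

from fractumor.cli_io import read_trajectory_csv
from fractumor.fitting import FitConfig, fit_alpha, fit_integer, spline_resample
from fractumor.growth_models import ModelKind
from fractumor.synthetic_data import MM3_PER_MODEL_UNIT

FIXTURES = Path("results/fixtures")
OUT = Path("results/sweeps")

if __name__ == "__main__":
    cfg = FitConfig()
    OUT.mkdir(parents=True, exist_ok=True)
    for arm in ("treated", "untreated"):
        t, v = read_trajectory_csv(FIXTURES / f"{arm}.csv")
        data = spline_resample(t, v / MM3_PER_MODEL_UNIT, cfg.grid_step)
        for kind in ModelKind:
            ifit = fit_integer(kind, data, config=cfg, v0=0.01)
            ffit, sweep = fit_alpha(kind, ifit.model.params, data,
                                    config=cfg, v0=0.01)
            path = OUT / f"sweep_{arm}_{kind.value}.csv"
            lines = ["alpha,mse"] + [f"{a:.12g},{m:.12g}"
                                     for a, m in zip(sweep.alphas, sweep.mses)]
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            interior = "interior" if ffit.alpha < 1.0 else "boundary (alpha=1)"
            print(f"{arm:10s} {kind.value:14s} alpha*={ffit.alpha:.2f} "
                  f"MSE={ffit.mse:.4g} ({interior} minimum)")
    print(f"wrote sweep curves to {OUT}/")
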