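#!/usr/bin/env python
"""Fit all five growth laws at integer order to the synthetic pair.

Stage one of the two-stage procedure: Nelder-Mead over each law's
kinetic parameters at alpha = 1, on the spline-resampled measurements,
with the near-zero initial-condition convention (v0 = 0.01 model
units).  Writes results/integer_fits.csv.

Run analysis/01_simulate_experiments.py first.
"""

from pathlib import Path

from fractumor.cli_io import read_trajectory_csv
from fractumor.fitting import FitConfig, fit_integer, spline_resample
from fractumor.growth_models import ModelKind
from fractumor.synthetic_data import MM3_PER_MODEL_UNIT

FIXTURES = Path("results/fixtures")
OUT = Path("results/integer_fits.csv")

if __name__ == "__main__":
    cfg = FitConfig()
    lines = ["dataset,model_kind,mse,params"]
    for arm in ("treated", "untreated"):
        t, v = read_trajectory_csv(FIXTURES / f"{arm}.csv")
        data = spline_resample(t, v / MM3_PER_MODEL_UNIT, cfg.grid_step)
        for kind in ModelKind:
            res = fit_integer(kind, data, config=cfg, v0=0.01)
            pstr = ";".join(f"{k}={v:.6g}" for k, v in res.model.params.items())
            lines.append(f"{arm},{kind.value},{res.mse:.6g},{pstr}")
            print(f"{arm:10s} {kind.value:14s} MSE={res.mse:.4g}  {pstr}")
    OUT.write_text("\n".join(lines) + "\n", encoding="utf-8")
    print(f"wrote {OUT}")
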