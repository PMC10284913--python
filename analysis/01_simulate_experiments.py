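#!/usr/bin/env python
"""Generate the synthetic treated/untreated murine experiment pair.

Writes two measurement CSVs (mm^3, 18-day horizon, 2-3 day cadence,
protocol-driven dosing in the treated arm) and a ground-truth manifest
under results/fixtures/.
"""

import json
from pathlib import Path

from fractumor.synthetic_data import make_fixture_pair

OUT = Path("results/fixtures")

if __name__ == "__main__":
    treated, untreated, manifest = make_fixture_pair(seed=1, out_dir=OUT)
    meta = json.loads(Path(manifest).read_text())
    print(f"wrote {treated} and {untreated}")
    print(f"true dynamics: fractional {meta['model_kind']} "
          f"(alpha={meta['alpha']}), params {meta['params']}")
    print(f"dose times (days): {meta['dose_times_days']}, "
          f"log-kill kappa={meta['kappa']}, noise sigma={meta['sigma']}")
    for name, path in (("treated", treated), ("untreated", untreated)):
        rows = Path(path).read_text().strip().splitlines()[1:]
        last_t, last_v = rows[-1].split(",")
        print(f"{name}: {len(rows)} measurements, "
              f"final volume {float(last_v):.0f} mm^3 at day {last_t}")
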