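"""Optimal aerobic->anaerobic switching time.

The batch productivity as a function of the switch time t_s rises to a
single maximum (a short aerobic phase leaves too few cells, a long one
wastes sugar on respiration) and the problem is solved as a bounded scalar
maximization with each objective evaluation being one full batch simulation.
A coarse grid pre-scan brackets the best basin before the golden-section/
parabolic refinement, guarding against stray local maxima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .dynamics import SimulationConfig, SpeciesSpec, simulate_batch
from .metrics import summarize

__all__ = ["SwitchResult", "optimize_switch", "productivity_curve"]


@dataclass
class SwitchResult:
    t_s_opt: float
    productivity_at_opt: float       # g/h
    evaluations: int
    bounds: tuple[float, float]


def _batch_productivity(t_s: float, conf: SimulationConfig,
                        yeast: SpeciesSpec, bacterium: SpeciesSpec) -> float:
    traj = simulate_batch(replace(conf, t_s=t_s), yeast, bacterium,
                          record_fluxes=False)
    return summarize(traj).productivity


def optimize_switch(conf: SimulationConfig, yeast: SpeciesSpec | None = None,
                    bacterium: SpeciesSpec | None = None,
                    bounds: tuple[float, float] | None = None,
                    tol: float = 0.01,
                    grid_points: int = 10,
                    objective: Callable[[float], float] | None = None,
                    ) -> SwitchResult:
    """Maximize batch productivity over the switching time.

    ``bounds`` defaults to (0, t_f). ``objective`` overrides the simulator
    (useful for testing against objectives with a known peak); by default it
    is one batch simulation + productivity per evaluation. A failed
    evaluation scores -inf with a warning and the search continues. The
    returned point is the best of everything evaluated (grid, refinement and
    both bounds), so its value is never below either endpoint's.
    """
    lo, hi = bounds if bounds is not None else (0.0, conf.t_f)
    if not lo < hi:
        raise ValueError(f"need t_LB < t_UB, got ({lo}, {hi})")
    if hi > conf.t_f:
        raise ValueError("upper bound exceeds the batch horizon t_f")
    if objective is None:
        if yeast is None or bacterium is None:
            raise ValueError("species specs required unless an objective is injected")
        objective = lambda ts: _batch_productivity(ts, conf, yeast, bacterium)

    evaluated: dict[float, float] = {}

    def safe(ts: float) -> float:
        ts = float(min(max(ts, lo), hi))
        if ts in evaluated:
            return evaluated[ts]
        try:
            val = float(objective(ts))
        except Exception as exc:  # a failed simulation is a bad point, not a crash
            warnings.warn(f"objective failed at t_s={ts:.4f} h: {exc}")
            val = -math.inf
        evaluated[ts] = val
        return val

    grid = np.linspace(lo, hi, max(grid_points, 2))
    grid_vals = [safe(t) for t in grid]
    k = int(np.argmax(grid_vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, len(grid) - 1)]
    if bhi - blo > tol:
        minimize_scalar(lambda t: -safe(t), bounds=(blo, bhi),
                        method="bounded", options={"xatol": tol})
    best_t = max(evaluated, key=evaluated.get)
    return SwitchResult(
        t_s_opt=best_t,
        productivity_at_opt=evaluated[best_t],
        evaluations=len(evaluated),
        bounds=(lo, hi),
    )


def productivity_curve(conf: SimulationConfig, yeast: SpeciesSpec,
                       bacterium: SpeciesSpec, t_s_values) -> "pd.DataFrame":
    """Batch productivity and ethanol over a grid of switching times."""
    import pandas as pd

    rows = []
    for ts in t_s_values:
        traj = simulate_batch(replace(conf, t_s=float(ts)), yeast, bacterium,
                              record_fluxes=False)
        m = summarize(traj)
        rows.append({"t_s": float(ts), "ethanol_g": m.ethanol_total,
                     "productivity_g_per_h": m.productivity,
                     "yield_g_per_g": m.yield_eth,
                     "glucose_final": m.glucose_final,
                     "xylose_final": m.xylose_final})
    return pd.DataFrame(rows)
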