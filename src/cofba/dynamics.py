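"""Batch coculture dynamics: extracellular mass balances around the inner LP.

The extracellular state is (X_SC, X_EC, G, Z, E): cellmass of the
glucose-selective yeast and the xylose-selective bacterium (gDW/L), glucose,
xylose and ethanol (g/L). At every derivative evaluation the uptake kinetics
convert concentrations into flux caps, each species' two-stage LP is solved,
and the exchange fluxes (mmol/gDW/h) are converted to mass rates through
(molar mass)/1000:

    dX/dt = mu X,   dC/dt = (M_w/1000) * v_C * X   (uptake negative)

Dissolved oxygen is an external control: held at the aerobic setpoint for
t < t_s and exactly 0 afterwards; no oxygen ODE is integrated, and the
integration is split at t_s so the discontinuity is never stepped across.
Cumulative secreted by-products (grams) are carried as extra states, which
also makes end-to-end carbon balances checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import config as cfg
from .fba_core import FluxSolution, TwoStageLP, solve_lexicographic
from .kinetics import KineticParams, uptake_bounds
from .model_io import MetabolicModel

__all__ = [
    "SpeciesSpec", "CocultureState", "SimulationConfig", "Trajectory",
    "IntegrationError", "rhs", "simulate_batch", "glucose_depletion_time",
]

_TRACKABLE = ("glycerol", "acetate", "formate", "lactate", "succinate", "co2")


class IntegrationError(RuntimeError):
    """Integrator step failure; carries the last valid state."""

    def __init__(self, message: str, last_state: "CocultureState"):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class SpeciesSpec:
    """One organism: its network, uptake kinetics and exchange naming.

    ``exchanges`` maps compound names ('glucose', 'xylose', 'oxygen',
    'ethanol', by-products, 'biomass') to the model's exchange reaction ids;
    only compounds the organism actually exchanges need to appear.
    """

    name: str
    model: MetabolicModel
    params: KineticParams
    exchanges: Mapping[str, str]

    def __post_init__(self):
        if "ethanol" not in self.exchanges:
            raise ValueError(f"species {self.name!r}: no ethanol exchange mapped")

    @property
    def tracked_products(self) -> tuple[str, ...]:
        return tuple(c for c in _TRACKABLE if c in self.exchanges)

    def with_model(self, model: MetabolicModel) -> "SpeciesSpec":
        return replace(self, model=model)


@dataclass
class CocultureState:
    """Extracellular snapshot at one time point."""

    t: float
    X_SC: float
    X_EC: float
    G: float
    Z: float
    E: float
    O: float  # dissolved oxygen (mM), policy-set


@dataclass(frozen=True)
class SimulationConfig:
    """Operating conditions and numerical settings for one batch."""

    t_f: float
    t_s: float
    glucose_0: float
    xylose_0: float
    inoculum_yeast: float = cfg.INOCULUM_YEAST
    inoculum_bacterium: float = cfg.INOCULUM_BACTERIUM
    o_aerobic: float = cfg.O_AEROBIC_MM
    volume: float = 1.0
    molar_masses: Mapping[str, float] = field(default_factory=lambda: dict(cfg.MOLAR_MASS))
    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: float = 0.25
    glucose_depletion_threshold: float = 0.1
    zero_conc: float = 1e-9
    solver: str = "glpk"  # "glpk" (persistent, warm-started) or "scipy"
    integrator: str = "rk23"  # "rk23" (adaptive) or "euler" (debug, fixed step)
    euler_step: float = 0.01  # h; only used by the Euler fallback

    def __post_init__(self):
        if not (0.0 <= self.t_s <= self.t_f):
            raise ValueError(f"need 0 <= t_s <= t_f, got t_s={self.t_s}, t_f={self.t_f}")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


def _species_caps(species: SpeciesSpec, G: float, Z: float, E: float, O: float,
                  zero_conc: float) -> dict[str, float]:
    G = G if G > zero_conc else 0.0
    Z = Z if Z > zero_conc else 0.0
    E = E if E > zero_conc else 0.0
    O = O if O > zero_conc else 0.0
    v = uptake_bounds(G, Z, E, O, species.params)
    caps = {}
    if "glucose" in species.exchanges:
        caps[species.exchanges["glucose"]] = v.v_g
    if "xylose" in species.exchanges:
        caps[species.exchanges["xylose"]] = v.v_z
    if "oxygen" in species.exchanges:
        caps[species.exchanges["oxygen"]] = v.v_o
    return caps


def _make_engines(species: Sequence[SpeciesSpec], solver: str):
    """Per-species two-stage solvers; the persistent GLPK engine re-solves
    from the previous basis and is the default for the inner dFBA loop."""
    if solver == "glpk":
        return {s.name: TwoStageLP(s.model, s.exchanges["ethanol"], s.exchanges).solve
                for s in species}
    if solver == "scipy":
        return {s.name: (lambda caps, s=s: solve_lexicographic(
            s.model, caps, s.exchanges["ethanol"], s.exchanges))
            for s in species}
    raise ValueError(f"unknown solver {solver!r}")


class _Layout:
    """State-vector layout: [X..., G, Z, cumulative grams per (species, product)]."""

    def __init__(self, species: Sequence[SpeciesSpec]):
        self.species = list(species)
        self.ix_X = {s.name: i for i, s in enumerate(species)}
        self.ix_G = len(species)
        self.ix_Z = len(species) + 1
        self.cum: list[tuple[str, str]] = []  # (species name, compound)
        for s in species:
            self.cum.append((s.name, "ethanol"))
            for p in s.tracked_products:
                self.cum.append((s.name, p))
        self.ix_cum = {key: self.ix_Z + 1 + k for k, key in enumerate(self.cum)}
        self.size = self.ix_Z + 1 + len(self.cum)

    def ethanol_conc(self, y: np.ndarray, volume: float) -> float:
        tot = sum(max(y[self.ix_cum[(s.name, "ethanol")]], 0.0) for s in self.species)
        return tot / volume

    def column(self, key: tuple[str, str]) -> str:
        return f"{key[1]}_{key[0]}_g"


def _rhs_vector(t: float, y: np.ndarray, layout: _Layout,
                conf: SimulationConfig, aerobic: bool, engines,
                solutions: list[FluxSolution] | None = None) -> np.ndarray:
    dydt = np.zeros_like(y)
    G = max(y[layout.ix_G], 0.0)
    Z = max(y[layout.ix_Z], 0.0)
    E = layout.ethanol_conc(y, conf.volume)
    O = conf.o_aerobic if aerobic else 0.0
    mm = conf.molar_masses
    for s in layout.species:
        X = max(y[layout.ix_X[s.name]], 0.0)
        if X == 0.0:
            if solutions is not None:
                solutions.append(FluxSolution(status="optimal", mu=0.0))
            continue
        sol = engines[s.name](_species_caps(s, G, Z, E, O, conf.zero_conc))
        if solutions is not None:
            solutions.append(sol)
        if not sol.optimal:
            continue  # e.g. maintenance unmet: species contributes no rates
        dydt[layout.ix_X[s.name]] = sol.mu * X
        ex = sol.exchanges
        if "glucose" in ex:
            dydt[layout.ix_G] += mm["glucose"] / 1000.0 * ex["glucose"] * X
        if "xylose" in ex:
            dydt[layout.ix_Z] += mm["xylose"] / 1000.0 * ex["xylose"] * X
        for _, compound in [k for k in layout.cum if k[0] == s.name]:
            flux = ex.get(compound, 0.0)
            dydt[layout.ix_cum[(s.name, compound)]] = (
                mm[compound] / 1000.0 * flux * X * conf.volume)
    return dydt


def rhs(state: CocultureState, conf: SimulationConfig,
        yeast: SpeciesSpec, bacterium: SpeciesSpec) -> dict[str, float]:
    """Named time-derivatives at one state (oxygen policy from state.O).

    Thin wrapper over the vectorized right-hand side used by the integrator;
    cumulative-product derivatives are reported under 'compound_species_g'.
    """
    layout = _Layout([yeast, bacterium])
    y = np.zeros(layout.size)
    y[layout.ix_X[yeast.name]] = state.X_SC
    y[layout.ix_X[bacterium.name]] = state.X_EC
    y[layout.ix_G] = state.G
    y[layout.ix_Z] = state.Z
    # distribute pre-existing ethanol over the ethanol counters (conc only
    # matters through the sum)
    y[layout.ix_cum[(yeast.name, "ethanol")]] = state.E * conf.volume
    engines = _make_engines(layout.species, conf.solver)
    dydt = _rhs_vector(state.t, y, layout, conf, state.O > 0.0, engines)
    out = {
        "X_SC": dydt[layout.ix_X[yeast.name]],
        "X_EC": dydt[layout.ix_X[bacterium.name]],
        "G": dydt[layout.ix_G],
        "Z": dydt[layout.ix_Z],
    }
    out["E"] = sum(dydt[layout.ix_cum[(s.name, "ethanol")]]
                   for s in layout.species) / conf.volume
    for key in layout.cum:
        out[layout.column(key)] = dydt[layout.ix_cum[key]]
    return out


@dataclass
class Trajectory:
    """Time series of extracellular states plus per-step flux solutions."""

    states: pd.DataFrame
    flux_records: list[tuple[FluxSolution, ...]]
    config: SimulationConfig
    species_names: tuple[str, ...]

    @property
    def final(self) -> pd.Series:
        return self.states.iloc[-1]

    def cumulative(self, compound: str, species: str) -> float:
        return float(self.final[f"{compound}_{species}_g"])

    def to_csv(self, path: str | Path) -> None:
        self.states.to_csv(path, index=False)


def simulate_batch(conf: SimulationConfig, yeast: SpeciesSpec,
                   bacterium: SpeciesSpec,
                   record_fluxes: bool = True) -> Trajectory:
    """Integrate the batch from 0 to t_f with the aerobic->anaerobic switch.

    Uses an adaptive low-order embedded pair (RK23) with the integration
    split exactly at t_s. Concentrations are clamped at zero; an infeasible
    species LP contributes zero rates. Raises :class:`IntegrationError` on
    step failure.
    """
    layout = _Layout([yeast, bacterium])
    engines = _make_engines(layout.species, conf.solver)
    y0 = np.zeros(layout.size)
    y0[layout.ix_X[yeast.name]] = conf.inoculum_yeast
    y0[layout.ix_X[bacterium.name]] = conf.inoculum_bacterium
    y0[layout.ix_G] = conf.glucose_0
    y0[layout.ix_Z] = conf.xylose_0

    phases = []
    if conf.t_s > 0:
        phases.append((0.0, min(conf.t_s, conf.t_f), True))
    if conf.t_s < conf.t_f:
        phases.append((conf.t_s, conf.t_f, False))

    times = [0.0]
    ys = [y0.copy()]
    aerobic_flags = [phases[0][2] if phases else True]
    y = y0
    for t0, t1, aerobic in phases:
        if conf.integrator == "euler":
            t_pts, y_pts = _euler(t0, t1, y, layout, conf, aerobic, engines)
        elif conf.integrator == "rk23":
            sol = solve_ivp(
                _rhs_vector, (t0, t1), y, method="RK23",
                rtol=conf.rtol, atol=conf.atol, max_step=conf.max_step,
                args=(layout, conf, aerobic, engines))
            if not sol.success:
                last = _state_from_vector(sol.t[-1], sol.y[:, -1], layout,
                                          conf, aerobic)
                raise IntegrationError(
                    f"integration failed at t={sol.t[-1]:.4f} h: {sol.message}",
                    last)
            t_pts, y_pts = sol.t, sol.y.T
        else:
            raise ValueError(f"unknown integrator {conf.integrator!r}")
        for k in range(1, len(t_pts)):
            times.append(float(t_pts[k]))
            ys.append(np.array(y_pts[k]))
            aerobic_flags.append(aerobic)
        y = np.array(y_pts[-1])

    Y = np.clip(np.array(ys), 0.0, None)
    data = {
        "t": times,
        "X_SC": Y[:, layout.ix_X[yeast.name]],
        "X_EC": Y[:, layout.ix_X[bacterium.name]],
        "G": Y[:, layout.ix_G],
        "Z": Y[:, layout.ix_Z],
    }
    data["E"] = (Y[:, layout.ix_cum[(yeast.name, "ethanol")]]
                 + Y[:, layout.ix_cum[(bacterium.name, "ethanol")]]) / conf.volume
    for key in layout.cum:
        data[layout.column(key)] = Y[:, layout.ix_cum[key]]
    frame = pd.DataFrame(data)

    records: list[tuple[FluxSolution, ...]] = []
    if record_fluxes:
        for k in range(len(times)):
            row = Y[k]
            sols: list[FluxSolution] = []
            _rhs_vector(times[k], row, layout, conf, aerobic_flags[k], engines,
                        solutions=sols)
            records.append(tuple(sols))
    return Trajectory(states=frame, flux_records=records, config=conf,
                      species_names=(yeast.name, bacterium.name))


def _euler(t0, t1, y0, layout, conf, aerobic, engines):
    """Fixed-step explicit Euler fallback (debugging aid, not for production)."""
    n = max(1, int(round((t1 - t0) / conf.euler_step)))
    h = (t1 - t0) / n
    t_pts = [t0]
    y_pts = [np.array(y0)]
    y = np.array(y0, dtype=float)
    for k in range(n):
        y = y + h * _rhs_vector(t0 + k * h, y, layout, conf, aerobic, engines)
        y = np.clip(y, 0.0, None)
        t_pts.append(t0 + (k + 1) * h)
        y_pts.append(y.copy())
    return np.array(t_pts), y_pts


def _state_from_vector(t, y, layout, conf, aerobic) -> CocultureState:
    return CocultureState(
        t=float(t),
        X_SC=float(y[0]), X_EC=float(y[1]),
        G=float(y[layout.ix_G]), Z=float(y[layout.ix_Z]),
        E=layout.ethanol_conc(y, conf.volume),
        O=conf.o_aerobic if aerobic else 0.0,
    )


def glucose_depletion_time(traj: Trajectory, threshold: float) -> float:
    """First time glucose drops below ``threshold`` g/L (linear interpolation).

    Returns ``math.inf`` if glucose never falls below the threshold.
    """
    t = traj.states["t"].to_numpy()
    G = traj.states["G"].to_numpy()
    if G.size == 0:
        raise ValueError("empty trajectory")
    below = G < threshold
    if not below.any():
        return math.inf
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    g0, g1 = G[k - 1], G[k]
    frac = (g0 - threshold) / (g0 - g1) if g1 != g0 else 1.0
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))
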