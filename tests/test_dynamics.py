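import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cofba.config import MOLAR_MASS
from cofba.dynamics import (CocultureState, SimulationConfig, Trajectory,
                            glucose_depletion_time, rhs, simulate_batch)
from cofba.kinetics import KineticParams, uptake_bounds
from cofba.synthetic_data import CARBON, toy_coculture


def _uninhibited(species):
    return dataclasses.replace(
        species, params=dataclasses.replace(species.params, K_ie=1e12))


def test_zero_inocula_freeze_the_batch(coculture_pair, short_conf):
    yeast, bact, _ = coculture_pair
    conf = dataclasses.replace(short_conf, inoculum_yeast=0.0,
                               inoculum_bacterium=0.0)
    traj = simulate_batch(conf, yeast, bact, record_fluxes=False)
    for col in ("X_SC", "X_EC", "G", "Z", "E"):
        assert traj.states[col].nunique() == 1


def test_rhs_scales_with_cellmass(coculture_pair, base_conf):
    yeast, bact, _ = coculture_pair
    dead = CocultureState(t=0.0, X_SC=0.0, X_EC=0.0, G=37.5, Z=37.5, E=0.0,
                          O=0.29)
    derivs = rhs(dead, base_conf, yeast, bact)
    assert all(v == 0.0 for v in derivs.values())
    alive = CocultureState(t=0.0, X_SC=0.1, X_EC=0.1, G=37.5, Z=37.5, E=0.0,
                           O=0.29)
    derivs = rhs(alive, base_conf, yeast, bact)
    assert derivs["X_SC"] > 0 and derivs["X_EC"] > 0
    assert derivs["G"] < 0 and derivs["Z"] < 0 and derivs["E"] > 0


def test_saturating_regime_matches_exponential_closed_form(coculture_pair):
    """Over a short horizon with inhibition disabled the caps are constant,
    so each species grows exponentially at the analytic optimum and every
    mass trajectory has a closed form."""
    yeast, bact, oracles = coculture_pair
    yeast, bact = _uninhibited(yeast), _uninhibited(bact)
    for t_s, o2_on in ((2.0, True), (0.0, False)):
        conf = SimulationConfig(t_f=2.0, t_s=t_s, glucose_0=37.5,
                                xylose_0=37.5)
        traj = simulate_batch(conf, yeast, bact, record_fluxes=False)
        fin = traj.final
        O = conf.o_aerobic if o2_on else 0.0
        expected_eth = 0.0
        for species, oracle, X0, sugar_conc, sugar_name, x_col in (
                (yeast, oracles["SC"], conf.inoculum_yeast, 37.5, "glucose", "X_SC"),
                (bact, oracles["EC"], conf.inoculum_bacterium, 37.5, "xylose", "X_EC")):
            v = uptake_bounds(sugar_conc if sugar_name == "glucose" else 0.0,
                              sugar_conc if sugar_name == "xylose" else 0.0,
                              0.0, O, species.params)
            cap = v.v_g if sugar_name == "glucose" else v.v_z
            ana = oracle.analytic_optimum(cap, v.v_o)
            growth = math.expm1(ana.mu * conf.t_f) / ana.mu * X0
            assert fin[x_col] == pytest.approx(X0 * math.exp(ana.mu * conf.t_f),
                                               rel=5e-3)
            consumed = MOLAR_MASS[sugar_name] / 1000.0 * cap * growth
            col = "G" if sugar_name == "glucose" else "Z"
            assert 37.5 - fin[col] == pytest.approx(consumed, rel=5e-3)
            expected_eth += MOLAR_MASS["ethanol"] / 1000.0 * ana.ethanol * growth
        total_eth = fin["ethanol_SC_g"] + fin["ethanol_EC_g"]
        assert total_eth == pytest.approx(expected_eth, rel=5e-3)


def test_substrate_selectivity_is_strict(coculture_pair, short_conf):
    yeast, bact, _ = coculture_pair
    only_bact = dataclasses.replace(short_conf, inoculum_yeast=0.0)
    traj = simulate_batch(only_bact, yeast, bact, record_fluxes=False)
    assert traj.states["G"].nunique() == 1          # bacterium never touches glucose
    assert traj.final["Z"] < short_conf.xylose_0
    only_yeast = dataclasses.replace(short_conf, inoculum_bacterium=0.0)
    traj = simulate_batch(only_yeast, yeast, bact, record_fluxes=False)
    assert traj.states["Z"].nunique() == 1          # yeast never touches xylose
    assert traj.final["G"] < short_conf.glucose_0


def test_states_stay_nonnegative_and_time_increases(coculture_pair, base_conf):
    yeast, bact, _ = coculture_pair
    traj = simulate_batch(base_conf, yeast, bact, record_fluxes=False)
    assert (traj.states.drop(columns="t").to_numpy() >= 0.0).all()
    assert (np.diff(traj.states["t"]) > 0).all()
    assert traj.states["t"].iloc[0] == 0.0


def test_oxygen_uptake_ceases_after_the_switch(coculture_pair, short_conf):
    yeast, bact, _ = coculture_pair
    traj = simulate_batch(short_conf, yeast, bact, record_fluxes=True)
    t = traj.states["t"].to_numpy()
    for k, sols in enumerate(traj.flux_records):
        for sol in sols:
            if not sol.optimal or sol.fluxes is None:
                continue
            o2 = sol.exchanges.get("oxygen", 0.0)
            if t[k] > short_conf.t_s:
                assert o2 == pytest.approx(0.0, abs=1e-9)
    aerobic_o2 = [sol.exchanges.get("oxygen", 0.0)
                  for k, sols in enumerate(traj.flux_records)
                  if t[k] < short_conf.t_s for sol in sols if sol.fluxes is not None]
    assert min(aerobic_o2) < -1.0  # oxygen actually consumed before the switch


def test_full_batch_carbon_balance(coculture_pair, base_conf):
    """Consumed sugar carbon reappears in cellmass, products and CO2 within
    0.5% - an end-to-end check of every unit conversion in the pipeline."""
    yeast, bact, _ = coculture_pair
    traj = simulate_batch(base_conf, yeast, bact, record_fluxes=False)
    fin = traj.final
    V = base_conf.volume
    mmol = lambda grams, name: grams / MOLAR_MASS[name] * 1000.0
    carbon_in = (mmol((base_conf.glucose_0 - fin["G"]) * V, "glucose") * 6
                 + mmol((base_conf.xylose_0 - fin["Z"]) * V, "xylose") * 5)
    carbon_out = 0.0
    for col in traj.states.columns:
        if col.endswith("_g"):
            compound = col[:-2].rsplit("_", 1)[0]
            carbon_out += mmol(fin[col], compound) * CARBON[
                {"ethanol": "etoh", "glycerol": "glyc", "acetate": "ac",
                 "formate": "for", "succinate": "succ", "co2": "co2"}[compound]]
    dX = (fin["X_SC"] - base_conf.inoculum_yeast
          + fin["X_EC"] - base_conf.inoculum_bacterium) * V
    carbon_out += mmol(dX, "biomass") * CARBON["biomass"]
    assert carbon_out == pytest.approx(carbon_in, rel=5e-3)


def test_tightening_tolerances_changes_little(coculture_pair, short_conf):
    yeast, bact, _ = coculture_pair
    loose = simulate_batch(short_conf, yeast, bact, record_fluxes=False)
    tight = simulate_batch(
        dataclasses.replace(short_conf, rtol=short_conf.rtol / 2,
                            atol=short_conf.atol / 2, max_step=short_conf.max_step / 2),
        yeast, bact, record_fluxes=False)
    e1 = loose.final["ethanol_SC_g"] + loose.final["ethanol_EC_g"]
    e2 = tight.final["ethanol_SC_g"] + tight.final["ethanol_EC_g"]
    assert abs(e1 - e2) / e2 < 1e-3


def test_euler_fallback_tracks_the_adaptive_integrator(coculture_pair, short_conf):
    yeast, bact, _ = coculture_pair
    rk = simulate_batch(short_conf, yeast, bact, record_fluxes=False)
    eu = simulate_batch(dataclasses.replace(short_conf, integrator="euler"),
                        yeast, bact, record_fluxes=False)
    assert eu.final["E"] == pytest.approx(rk.final["E"], rel=2e-2)
    assert eu.final["X_SC"] == pytest.approx(rk.final["X_SC"], rel=2e-2)


def _fake_trajectory(t, G, conf):
    frame = pd.DataFrame({"t": t, "G": G})
    return Trajectory(states=frame, flux_records=[], config=conf,
                      species_names=("SC", "EC"))


def test_glucose_depletion_time_interpolates(short_conf):
    traj = _fake_trajectory([0.0, 0.5, 1.0], [1.0, 0.5, 0.0], short_conf)
    assert glucose_depletion_time(traj, 0.1) == pytest.approx(0.9)
    flat = _fake_trajectory([0.0, 1.0], [5.0, 5.0], short_conf)
    assert glucose_depletion_time(flat, 0.1) == math.inf


def test_base_case_depletes_glucose_within_horizon(coculture_pair, base_conf):
    yeast, bact, _ = coculture_pair
    traj = simulate_batch(base_conf, yeast, bact, record_fluxes=False)
    t_dep = glucose_depletion_time(traj, base_conf.glucose_depletion_threshold)
    assert 0.0 < t_dep <= base_conf.t_f


def test_config_validation():
    with pytest.raises(ValueError, match="t_s"):
        SimulationConfig(t_f=10.0, t_s=12.0, glucose_0=10, xylose_0=10)
    with pytest.raises(ValueError, match="volume"):
        SimulationConfig(t_f=10.0, t_s=5.0, glucose_0=10, xylose_0=10, volume=0)
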