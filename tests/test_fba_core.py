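import numpy as np
import pytest

from cofba.fba_core import (TwoStageLP, solve_coculture, solve_growth,
                            solve_lexicographic, variability_at_optimum)
from cofba.synthetic_data import (bacterium_toy_spec, exchange_map,
                                  make_toy_model, oracle_lexicographic,
                                  yeast_toy_spec)

YEAST_CAPS = [{"EX_glc": 22.4, "EX_o2": 0.0},
              {"EX_glc": 22.4, "EX_o2": 2.474},
              {"EX_glc": 5.0, "EX_o2": 10.0}]
BACT_CAPS = [{"EX_xyl": 12.0, "EX_o2": 0.0},
             {"EX_xyl": 12.0, "EX_o2": 20.0},
             {"EX_xyl": 3.0, "EX_o2": 1.0}]


def test_growth_matches_analytic_optimum(toy_yeast, toy_bact):
    for (model, oracle), caps_list, sugar_ex in [
            (toy_yeast, YEAST_CAPS, "EX_glc"), (toy_bact, BACT_CAPS, "EX_xyl")]:
        for caps in caps_list:
            sol = solve_growth(model, caps)
            ana = oracle.analytic_optimum(caps[sugar_ex], caps["EX_o2"])
            assert sol.status == "optimal"
            assert sol.mu == pytest.approx(ana.mu, abs=1e-8)


def test_two_stage_matches_vertex_enumeration(toy_yeast, toy_bact_small):
    for (model, _), caps_list, sugar_ex in [
            (toy_yeast, YEAST_CAPS, "EX_glc"),
            (toy_bact_small, BACT_CAPS, "EX_xyl")]:
        for caps in caps_list:
            mu_o, eth_o = oracle_lexicographic(model, caps, "EX_etoh")
            sol = solve_lexicographic(model, caps, "EX_etoh")
            assert sol.mu == pytest.approx(mu_o, abs=1e-8)
            assert sol.flux("EX_etoh") == pytest.approx(eth_o, abs=1e-7)


def test_steady_state_residual_and_bounds(toy_bact):
    model, _ = toy_bact
    for caps in BACT_CAPS:
        sol = solve_lexicographic(model, caps, "EX_etoh")
        residual = np.abs(model.stoichiometry @ sol.fluxes).max()
        assert residual <= 1e-6
        lb = model.lower_bounds.copy()
        lb[model.reaction_index("EX_xyl")] = -caps["EX_xyl"]
        lb[model.reaction_index("EX_o2")] = -caps["EX_o2"]
        assert np.all(sol.fluxes >= lb - 1e-9)
        assert np.all(sol.fluxes <= model.upper_bounds + 1e-9)


def test_zero_caps_give_zero_growth_or_infeasibility():
    free, _ = make_toy_model(yeast_toy_spec())
    sol = solve_growth(free, {"EX_glc": 0.0, "EX_o2": 0.0})
    assert sol.status == "optimal" and sol.mu == pytest.approx(0.0, abs=1e-12)
    needy, _ = make_toy_model(yeast_toy_spec(maintenance=1.0))
    sol = solve_growth(needy, {"EX_glc": 0.0, "EX_o2": 0.0})
    assert sol.status == "infeasible"


def test_doubling_caps_doubles_growth(toy_yeast):
    model, _ = toy_yeast  # maintenance-free, so the LP scales linearly
    for caps in YEAST_CAPS:
        mu1 = solve_growth(model, caps).mu
        mu2 = solve_growth(model, {k: 2 * v for k, v in caps.items()}).mu
        assert mu2 == pytest.approx(2 * mu1, rel=1e-9)


def test_stage2_keeps_growth_and_never_loses_ethanol(toy_yeast, toy_bact):
    for model, _ in (toy_yeast, toy_bact):
        caps_list = YEAST_CAPS if "glc" in model.metabolite_ids else BACT_CAPS
        for caps in caps_list:
            one = solve_growth(model, caps)
            two = solve_lexicographic(model, caps, "EX_etoh")
            assert abs(two.mu - one.mu) <= 1e-6
            assert two.flux("EX_etoh") >= one.flux("EX_etoh") - 1e-9


def test_degenerate_optimum_resolved_toward_ethanol():
    model, oracle = make_toy_model(yeast_toy_spec(degenerate=True))
    caps = {"EX_glc": 10.0, "EX_o2": 0.0}
    ana = oracle.analytic_optimum(10.0, 0.0)
    lo, hi = ana.stage1_ethanol_range
    assert hi > lo  # the growth optimum is a genuine face
    sol = solve_lexicographic(model, caps, "EX_etoh")
    assert sol.flux("EX_etoh") == pytest.approx(hi, abs=1e-7)
    mu_o, eth_o = oracle_lexicographic(model, caps, "EX_etoh")
    assert sol.mu == pytest.approx(mu_o, abs=1e-8)
    assert sol.flux("EX_etoh") == pytest.approx(eth_o, abs=1e-7)


def test_variability_flags_degeneracy_then_clears_it():
    model, _ = make_toy_model(yeast_toy_spec(degenerate=True))
    caps = {"EX_glc": 10.0, "EX_o2": 0.0}
    stage1 = variability_at_optimum(model, caps, reactions=["EX_etoh"])
    lo, hi = stage1["EX_etoh"]
    assert hi - lo > 1e-6
    stage2 = variability_at_optimum(model, caps, ethanol_id="EX_etoh",
                                    fix_ethanol=True, reactions=["EX_etoh"])
    lo2, hi2 = stage2["EX_etoh"]
    assert hi2 - lo2 <= 1e-5


def test_cap_on_non_exchange_reaction_rejected(toy_yeast):
    model, _ = toy_yeast
    with pytest.raises(ValueError, match="non-exchange"):
        solve_growth(model, {"FERM": 5.0})
    with pytest.raises(ValueError, match="negative uptake cap"):
        solve_growth(model, {"EX_glc": -1.0})


def test_coculture_equals_independent_solves(toy_yeast, toy_bact):
    ym, _ = toy_yeast
    bm, _ = toy_bact
    caps = ({"EX_glc": 22.4, "EX_o2": 2.474}, {"EX_xyl": 12.0, "EX_o2": 19.8})
    joint = solve_coculture((ym, bm), caps, ethanol_ids=("EX_etoh", "EX_etoh"))
    indep = (solve_lexicographic(ym, caps[0], "EX_etoh"),
             solve_lexicographic(bm, caps[1], "EX_etoh"))
    for j, i in zip(joint, indep):
        assert j.mu == pytest.approx(i.mu, abs=1e-9)
        assert j.flux("EX_etoh") == pytest.approx(i.flux("EX_etoh"), abs=1e-8)
    # combined objective is the sum of the species' growth rates
    block = solve_coculture((ym, bm), caps)
    growth = (solve_growth(ym, caps[0]), solve_growth(bm, caps[1]))
    assert block[0].mu + block[1].mu == pytest.approx(
        growth[0].mu + growth[1].mu, abs=1e-8)


def test_coculture_isolates_per_species_infeasibility(toy_yeast):
    ym, _ = toy_yeast
    needy, _ = make_toy_model(bacterium_toy_spec(maintenance=5.0))
    caps = ({"EX_glc": 10.0, "EX_o2": 1.0}, {"EX_xyl": 0.0, "EX_o2": 0.0})
    a, b = solve_coculture((ym, needy), caps, ethanol_ids=("EX_etoh", "EX_etoh"))
    assert a.status == "optimal" and a.mu > 0
    assert b.status == "infeasible"


def test_persistent_engine_matches_one_shot_solver(toy_yeast, toy_bact):
    rng = np.random.default_rng(7)
    for model, _ in (toy_yeast, toy_bact):
        sugar_ex = "EX_glc" if "glc" in model.metabolite_ids else "EX_xyl"
        engine = TwoStageLP(model, "EX_etoh", exchange_map(model))
        for _ in range(20):
            caps = {sugar_ex: float(rng.uniform(0, 25)),
                    "EX_o2": float(rng.uniform(0, 20))}
            fast = engine.solve(caps)
            ref = solve_lexicographic(model, caps, "EX_etoh")
            assert fast.status == ref.status == "optimal"
            assert fast.mu == pytest.approx(ref.mu, abs=1e-8)
            assert fast.flux("EX_etoh") == pytest.approx(ref.flux("EX_etoh"),
                                                         abs=1e-7)
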