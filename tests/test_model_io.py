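import json

import numpy as np
import pytest

from cofba.fba_core import solve_growth, solve_lexicographic
from cofba.model_io import (MetabolicModel, ModelFormatError, ReactionSpec,
                            UnknownReactionError, apply_deletions,
                            apply_insertion, make_xylose_selective, read_model,
                            resolve_reaction, write_model)
from cofba.synthetic_data import exchange_map


def _dense(model):
    return model.stoichiometry.toarray()


@pytest.mark.parametrize("fmt,suffix", [("json", ".json"), ("sbml", ".xml")])
def test_round_trip_preserves_matrix_bounds_objective(toy_yeast, tmp_path, fmt, suffix):
    model, _ = toy_yeast
    path = tmp_path / f"toy{suffix}"
    write_model(model, path, format=fmt)
    back = read_model(path, format=fmt)
    assert back.metabolite_ids == model.metabolite_ids
    assert back.reaction_ids == model.reaction_ids
    np.testing.assert_allclose(_dense(back), _dense(model))
    np.testing.assert_allclose(back.lower_bounds, model.lower_bounds)
    np.testing.assert_allclose(back.upper_bounds, model.upper_bounds)
    np.testing.assert_allclose(back.objective_weights, model.objective_weights)
    assert set(back.exchange_ids) == set(model.exchange_ids)


def test_one_reaction_file_gives_expected_matrix(tmp_path):
    doc = {
        "id": "mini", "version": "1",
        "metabolites": [
            {"id": "A_c", "name": "A", "compartment": "c"},
            {"id": "B_c", "name": "B", "compartment": "c"}],
        "reactions": [{
            "id": "R_AB", "name": "A to B", "metabolites": {"A_c": -1, "B_c": 1},
            "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": "",
            "objective_coefficient": 1}],
        "genes": [], "compartments": {"c": "c"},
    }
    path = tmp_path / "mini.json"
    path.write_text(json.dumps(doc))
    model = read_model(path)
    assert _dense(model).shape == (2, 1)
    np.testing.assert_allclose(_dense(model).ravel(), [-1.0, 1.0])


def test_missing_objective_is_a_clear_error(tmp_path):
    doc = {
        "id": "noobj", "version": "1",
        "metabolites": [{"id": "A_c", "name": "A", "compartment": "c"}],
        "reactions": [{"id": "EX_A", "name": "", "metabolites": {"A_c": -1},
                       "lower_bound": -10, "upper_bound": 10,
                       "gene_reaction_rule": "", "objective_coefficient": 0}],
        "genes": [], "compartments": {"c": "c"},
    }
    path = tmp_path / "noobj.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelFormatError, match="no biomass reaction"):
        read_model(path)


def test_unparsable_file_raises_format_error(tmp_path):
    path = tmp_path / "garbage.json"
    path.write_text("this is not a model {")
    with pytest.raises(ModelFormatError):
        read_model(path)
    with pytest.raises(FileNotFoundError):
        read_model(tmp_path / "does_not_exist.json")


def test_deletions_zero_bounds_without_mutating_input(toy_bact, alias_map):
    model, _ = toy_bact
    before = model.lower_bounds.copy(), model.upper_bounds.copy()
    edited = apply_deletions(model, ["pfl"], alias_map)
    j = edited.reaction_index("FERM_MIX")
    assert edited.lower_bounds[j] == edited.upper_bounds[j] == 0.0
    np.testing.assert_array_equal(model.lower_bounds, before[0])
    np.testing.assert_array_equal(model.upper_bounds, before[1])


def test_empty_deletion_list_is_identity(toy_yeast):
    model, _ = toy_yeast
    same = apply_deletions(model, [])
    np.testing.assert_allclose(_dense(same), _dense(model))
    np.testing.assert_array_equal(same.lower_bounds, model.lower_bounds)


def test_unknown_reaction_lists_similar_candidates(toy_yeast):
    model, _ = toy_yeast
    with pytest.raises(UnknownReactionError, match="FERM"):
        apply_deletions(model, ["FERM_TYPO"])


def test_alias_resolution_requires_unique_candidate(toy_bact, alias_map):
    model, _ = toy_bact
    assert resolve_reaction(model, "pfl", alias_map) == "FERM_MIX"
    with pytest.raises(UnknownReactionError, match="none of the candidates"):
        resolve_reaction(model, "fum", alias_map)
    # a model containing two candidates for one alias is ambiguous
    two = apply_insertion(model, ReactionSpec(id="PFL", stoichiometry={"atp": -1}))
    with pytest.raises(UnknownReactionError, match="ambiguous"):
        resolve_reaction(two, "pfl", alias_map)


def test_insertion_appends_column_with_convention_bounds(toy_yeast):
    model, _ = toy_yeast
    spec = ReactionSpec(id="NEW_RXN", stoichiometry={"glc": -1, "co2": 6},
                        reversible=True)
    bigger = apply_insertion(model, spec)
    assert bigger.n_reactions == model.n_reactions + 1
    j = bigger.reaction_index("NEW_RXN")
    assert (bigger.lower_bounds[j], bigger.upper_bounds[j]) == (-1000.0, 1000.0)
    irr = apply_insertion(model, ReactionSpec(id="NEW2", stoichiometry={"glc": -1, "co2": 6}))
    j2 = irr.reaction_index("NEW2")
    assert (irr.lower_bounds[j2], irr.upper_bounds[j2]) == (0.0, 1000.0)
    assert model.n_reactions == bigger.n_reactions - 1  # input untouched


def test_insertion_rejects_duplicates_and_unknown_metabolites(toy_yeast):
    model, _ = toy_yeast
    with pytest.raises(ValueError, match="already present"):
        apply_insertion(model, ReactionSpec(id="FERM", stoichiometry={"glc": -1}))
    with pytest.raises(KeyError, match="nadph"):
        apply_insertion(model, ReactionSpec(id="X", stoichiometry={"nadph_c": 1}))
    created = apply_insertion(
        model, ReactionSpec(id="X", stoichiometry={"nadph_c": 1}),
        create_missing_metabolites=True)
    assert "nadph_c" in created.metabolite_ids


def test_insert_then_delete_leaves_optimum_unchanged(toy_yeast):
    model, _ = toy_yeast
    caps = {"EX_glc": 10.0, "EX_o2": 1.0}
    base = solve_lexicographic(model, caps, "EX_etoh")
    spec = ReactionSpec(id="INERT", stoichiometry={"glc": -1, "co2": 6})
    edited = apply_deletions(apply_insertion(model, spec), ["INERT"])
    after = solve_lexicographic(edited, caps, "EX_etoh")
    assert after.mu == pytest.approx(base.mu, abs=1e-9)
    assert after.flux("EX_etoh") == pytest.approx(base.flux("EX_etoh"), abs=1e-8)


def test_xylose_selective_passes_through_glucose_free_model(toy_bact, alias_map):
    model, _ = toy_bact
    once = make_xylose_selective(model, alias_map, strict=False)
    np.testing.assert_array_equal(once.lower_bounds, model.lower_bounds)
    twice = make_xylose_selective(once, alias_map, strict=False)
    np.testing.assert_array_equal(twice.lower_bounds, once.lower_bounds)
    sol = solve_growth(once, {"EX_xyl": 12.0, "EX_o2": 0.0})
    ref = solve_growth(model, {"EX_xyl": 12.0, "EX_o2": 0.0})
    assert sol.mu == pytest.approx(ref.mu, abs=1e-10)


def test_xylose_selective_strict_requires_both_reactions(toy_yeast, alias_map):
    model, _ = toy_yeast  # has a glucose exchange but no glucokinase
    with pytest.raises(UnknownReactionError):
        make_xylose_selective(model, alias_map, strict=True)
    relaxed = make_xylose_selective(model, alias_map, strict=False)
    j = relaxed.reaction_index("EX_glc")
    assert relaxed.lower_bounds[j] == relaxed.upper_bounds[j] == 0.0


def test_dimension_check_flags_model_version_mismatches(toy_yeast):
    from cofba.model_io import check_dimensions

    model, _ = toy_yeast
    check_dimensions(model, model.n_metabolites, model.n_reactions,
                     len(model.exchange_ids))
    with pytest.raises(ValueError, match="expected"):
        check_dimensions(model, model.n_metabolites + 1, model.n_reactions)
    with pytest.raises(ValueError, match="exchange"):
        check_dimensions(model, model.n_metabolites, model.n_reactions,
                         len(model.exchange_ids) - 1)


def test_cobra_agrees_with_growth_solver(toy_yeast, tmp_path):
    """Independent cross-check: the same file solved by cobrapy/GLPK."""
    import cobra.io

    model, _ = toy_yeast
    caps = {"EX_glc": 22.4, "EX_o2": 2.474}
    ours = solve_growth(model, caps)
    path = tmp_path / "toy.json"
    write_model(model, path)
    cm = cobra.io.load_json_model(str(path))
    cm.reactions.EX_glc.lower_bound = -22.4
    cm.reactions.EX_o2.lower_bound = -2.474
    sol = cm.optimize()
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(ours.mu, rel=1e-7)
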