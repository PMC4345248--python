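"""Stoichiometric model container, file I/O, and reaction-level edits.

The in-memory representation is deliberately minimal: a sparse stoichiometric
matrix ``A`` (rows = metabolites, columns = reactions; products positive,
substrates negative), per-reaction flux bounds in mmol/gDW/h, and a vector of
objective weights that is nonzero only on the biomass pseudo-reaction.
Genome-scale files (SBML Level 3 FBC or COBRA model-JSON) are read and
written through cobrapy; all edits (deletions, insertions, substrate
selectivity) are value-semantic and never mutate their input.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

__all__ = [
    "MetabolicModel",
    "ReactionSpec",
    "ModelFormatError",
    "UnknownReactionError",
    "read_model",
    "write_model",
    "apply_deletions",
    "apply_insertion",
    "make_xylose_selective",
    "load_alias_map",
    "resolve_reaction",
    "check_dimensions",
]

#: Default bound magnitude for inserted reactions (genome-scale convention).
DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """A model file could not be parsed in the declared format."""


class UnknownReactionError(KeyError):
    """A reaction id (or alias) did not resolve to exactly one reaction."""


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction to insert: id, stoichiometry, reversibility, compartment."""

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    compartment: str = "c"
    name: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.id!r}: zero coefficient")


@dataclass
class MetabolicModel:
    """A stoichiometric metabolic network with bounds and a growth objective.

    Attributes
    ----------
    stoichiometry:
        ``m x n`` sparse matrix; entry (i, j) is the coefficient of
        metabolite i in reaction j (products > 0, substrates < 0).
    lower_bounds, upper_bounds:
        Per-reaction flux bounds (mmol/gDW/h). For exchange reactions the
        convention is negative flux = uptake, positive = secretion.
    objective_weights:
        Per-reaction weights ``w``; growth rate is ``w @ v``.
    exchange_ids:
        Reactions crossing the system boundary.
    metabolite_formulas:
        Optional elemental formulas (used for carbon-balance checks).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_weights: np.ndarray
    exchange_ids: list[str]
    name: str = ""
    metabolite_formulas: dict[str, str] = field(default_factory=dict)
    _rxn_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.stoichiometry = sp.csc_matrix(self.stoichiometry, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_weights = np.asarray(self.objective_weights, dtype=float)
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        m, n = self.stoichiometry.shape
        if len(self.metabolite_ids) != m:
            raise ValueError("metabolite count does not match matrix rows")
        if len(self.reaction_ids) != n:
            raise ValueError("reaction count does not match matrix columns")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n:
            raise ValueError("duplicate reaction ids")
        for vec, label in ((self.lower_bounds, "lower"), (self.upper_bounds, "upper"),
                           (self.objective_weights, "objective")):
            if vec.shape != (n,):
                raise ValueError(f"{label} vector has wrong length")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = self.reaction_ids[int(np.argmax(self.lower_bounds > self.upper_bounds))]
            raise ValueError(f"lower bound exceeds upper bound for {bad!r}")
        if not np.any(self.objective_weights):
            raise ValueError("no biomass reaction: objective weights are all zero")
        unknown = set(self.exchange_ids) - set(self.reaction_ids)
        if unknown:
            raise ValueError(f"exchange ids not in reaction list: {sorted(unknown)}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            candidates = difflib.get_close_matches(reaction_id, self.reaction_ids, n=5)
            raise UnknownReactionError(
                f"no reaction {reaction_id!r} in model {self.name!r};"
                f" closest ids: {candidates}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_weights=self.objective_weights.copy(),
            exchange_ids=list(self.exchange_ids),
            name=self.name,
            metabolite_formulas=dict(self.metabolite_formulas),
        )


# ---------------------------------------------------------------------------
# file I/O (through cobrapy)
# ---------------------------------------------------------------------------

def _from_cobra(cm) -> MetabolicModel:
    import cobra

    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    w = np.zeros(len(rxn_ids))
    exchange = []
    for j, r in enumerate(cm.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        w[j] = r.objective_coefficient
        if r.boundary:
            exchange.append(r.id)
        for met, coef in r.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coef))
    A = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    formulas = {m.id: m.formula for m in cm.metabolites if m.formula}
    if not np.any(w):
        raise ModelFormatError(
            f"model {cm.id!r} declares no biomass reaction (zero objective)")
    return MetabolicModel(met_ids, rxn_ids, A, lb, ub, w, exchange,
                          name=cm.id or "", metabolite_formulas=formulas)


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.name or "model")
    mets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1] if "_" in mid else "c")
        formula = model.metabolite_formulas.get(mid)
        if formula:
            met.formula = formula
        mets[mid] = met
    cm.add_metabolites(list(mets.values()))
    A = model.stoichiometry.tocsc()
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        col = A.getcol(j)
        rxn.add_metabolites({mets[model.metabolite_ids[i]]: float(v)
                             for i, v in zip(col.indices, col.data)})
        rxns.append(rxn)
    cm.add_reactions(rxns)
    from cobra.util.solver import set_objective

    objective = {}
    for j, wj in enumerate(model.objective_weights):
        if wj:
            objective[cm.reactions.get_by_id(model.reaction_ids[j])] = float(wj)
    set_objective(cm, objective)
    return cm


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read an SBML (L3 FBC) or COBRA model-JSON file.

    ``format`` is one of ``{"sbml", "json"}``; if omitted it is inferred from
    the file suffix. All reactions, bounds and the biomass objective are
    taken from the file; metabolites unused by any reaction are retained.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format not in {"sbml", "json"}:
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "json":
            cm = cobra.io.load_json_model(str(path))
        else:
            cm = cobra.io.read_sbml_model(str(path))
    except ModelFormatError:
        raise
    except Exception as exc:  # parser errors carry the offending element
        raise ModelFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_cobra(cm)


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    """Write a model as SBML or COBRA model-JSON (round-trip safe)."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    cm = _to_cobra(model)
    if format == "json":
        cobra.io.save_json_model(cm, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def check_dimensions(model: MetabolicModel, n_metabolites: int,
                     n_reactions: int, n_exchanges: int | None = None) -> None:
    """Assert a loaded model has the published structural dimensions.

    Genome-scale reconstructions are distributed in several revisions;
    comparing the stoichiometric matrix shape and exchange count against the
    published figures catches loading a mismatched model version early.
    Raises ``ValueError`` on any mismatch.
    """
    got = (model.n_metabolites, model.n_reactions)
    if got != (n_metabolites, n_reactions):
        raise ValueError(
            f"model {model.name!r} is {got[0]} x {got[1]}, expected"
            f" {n_metabolites} x {n_reactions}")
    if n_exchanges is not None and len(model.exchange_ids) != n_exchanges:
        raise ValueError(
            f"model {model.name!r} has {len(model.exchange_ids)} exchange"
            f" reactions, expected {n_exchanges}")


# ---------------------------------------------------------------------------
# alias resolution
# ---------------------------------------------------------------------------

def load_alias_map(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the enzyme-name -> candidate-reaction-id map (YAML).

    Genome-scale files use database-specific reaction ids while strategies
    are stated as enzyme names; each alias lists candidate ids across model
    versions plus the toy-model id, of which exactly one must be present in
    any given model.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "aliases.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: list(v) for k, v in raw.items()}


def resolve_reaction(model: MetabolicModel, name: str,
                     alias_map: Mapping[str, Sequence[str]] | None = None) -> str:
    """Resolve a reaction id or alias to the unique matching model reaction.

    Exact ids win; otherwise the alias candidates are matched against the
    model and exactly one must be present (zero or several is an error).
    """
    if name in model._rxn_index:
        return name
    if alias_map and name in alias_map:
        hits = [c for c in alias_map[name] if c in model._rxn_index]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise UnknownReactionError(
                f"alias {name!r} is ambiguous in model {model.name!r}: {hits}")
        raise UnknownReactionError(
            f"alias {name!r}: none of the candidates {list(alias_map[name])}"
            f" are in model {model.name!r}")
    candidates = difflib.get_close_matches(name, model.reaction_ids, n=5)
    raise UnknownReactionError(
        f"no reaction or alias {name!r} in model {model.name!r};"
        f" closest ids: {candidates}")


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------

def apply_deletions(model: MetabolicModel, reaction_ids: Sequence[str],
                    alias_map: Mapping[str, Sequence[str]] | None = None,
                    ) -> MetabolicModel:
    """Return a copy with the named reactions constrained to zero flux.

    Each entry may be a model reaction id or an alias-map key. The input
    model is never modified.
    """
    out = model.copy()
    for name in reaction_ids:
        j = out.reaction_index(resolve_reaction(out, name, alias_map))
        out.lower_bounds[j] = 0.0
        out.upper_bounds[j] = 0.0
    return out


def apply_insertion(model: MetabolicModel, spec: ReactionSpec,
                    default_bound: float = DEFAULT_BOUND,
                    create_missing_metabolites: bool = False) -> MetabolicModel:
    """Return a copy with one reaction column appended.

    Bounds are ``(-M, +M)`` if the reaction is reversible, ``(0, +M)``
    otherwise, with ``M = default_bound``.
    """
    if spec.id in model._rxn_index:
        raise ValueError(f"reaction id {spec.id!r} already present in model")
    missing = [m for m in spec.stoichiometry if m not in set(model.metabolite_ids)]
    if missing and not create_missing_metabolites:
        raise KeyError(
            f"metabolites {missing} not in model {model.name!r}"
            " (pass create_missing_metabolites=True to add them)")

    met_ids = list(model.metabolite_ids) + missing
    met_pos = {m: i for i, m in enumerate(met_ids)}
    A = sp.lil_matrix((len(met_ids), model.n_reactions + 1))
    A[: model.n_metabolites, : model.n_reactions] = model.stoichiometry
    for mid, coef in spec.stoichiometry.items():
        A[met_pos[mid], model.n_reactions] = coef
    lb = np.append(model.lower_bounds, -default_bound if spec.reversible else 0.0)
    ub = np.append(model.upper_bounds, default_bound)
    w = np.append(model.objective_weights, 0.0)
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=list(model.reaction_ids) + [spec.id],
        stoichiometry=A.tocsc(),
        lower_bounds=lb,
        upper_bounds=ub,
        objective_weights=w,
        exchange_ids=list(model.exchange_ids),
        name=model.name,
        metabolite_formulas=dict(model.metabolite_formulas),
    )


def make_xylose_selective(model: MetabolicModel,
                          alias_map: Mapping[str, Sequence[str]] | None = None,
                          strict: bool = True) -> MetabolicModel:
    """Constrain glucose exchange and glucokinase fluxes to zero.

    This reproduces, at reaction level, a glucose-transport-negative strain:
    the organism can no longer take up or phosphorylate glucose and grows on
    xylose only. Idempotent. With ``strict=False`` a model containing none of
    the glucose-reaction candidates is considered already selective and is
    returned unchanged (as a copy).
    """
    alias_map = alias_map or load_alias_map()
    targets = []
    for alias in ("glucose_exchange", "glucokinase"):
        try:
            targets.append(resolve_reaction(model, alias, alias_map))
        except UnknownReactionError:
            if strict:
                raise
    return apply_deletions(model, targets)
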