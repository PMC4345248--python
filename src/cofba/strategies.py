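"""Genetic-strategy catalogue and the strategy x mixture scan driver.

The catalogue holds sixteen engineering strategies: ten reaction deletions
in the xylose-selective bacterium that redirect carbon from acetate,
formate, lactate or succinate towards ethanol (acetate kinase, pyruvate
formate lyase, phosphotransacetylase, and double deletions built on them);
two NADP-dependent dehydrogenase insertions in the yeast that displace
glycerol formation as the redox sink (glycerol-3-phosphate dehydrogenase,
R00845, and non-phosphorylating glyceraldehyde-3-phosphate dehydrogenase,
R01058); and the four pairings of an insertion with a single deletion.
Strategies name enzymes; the alias map resolves them to reaction ids in
whichever model is loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import config as cfg
from .dynamics import SimulationConfig, SpeciesSpec, simulate_batch
from .metrics import summarize
from .model_io import (ReactionSpec, apply_deletions, apply_insertion,
                       load_alias_map)
from .optimization import optimize_switch

__all__ = ["GeneticStrategy", "catalogue", "apply_strategy", "run_scan",
           "strategy_to_yaml", "strategy_from_yaml"]


@dataclass(frozen=True)
class GeneticStrategy:
    """A named set of reaction deletions and/or insertions."""

    name: str
    target_species: str                       # "yeast" | "bacterium" | "both"
    deletions: tuple[str, ...] = ()           # alias-map keys
    insertions: tuple[ReactionSpec, ...] = ()

    def __post_init__(self):
        if not self.deletions and not self.insertions:
            raise ValueError(f"strategy {self.name!r} edits nothing")
        if self.target_species not in {"yeast", "bacterium", "both"}:
            raise ValueError(f"bad target species {self.target_species!r}")


# Inserted-reaction chemistry, written with cytosolic metabolite ids as used
# by the compartmentalized yeast network.
R00845 = ReactionSpec(
    id="R00845",
    name="NADP-dependent glycerol-3-phosphate dehydrogenase",
    stoichiometry={"glyc3p_c": -1, "nadp_c": -1, "g3p_c": 1, "nadph_c": 1},
    reversible=True,
    compartment="c",
)
R01058 = ReactionSpec(
    id="R01058",
    name="non-phosphorylating NADP-dependent G3P dehydrogenase (GAPN)",
    stoichiometry={"g3p_c": -1, "nadp_c": -1, "3pg_c": 1, "nadph_c": 1},
    reversible=False,
    compartment="c",
)

_DELETIONS = [
    ("dack", ("ack",)),
    ("dpfl", ("pfl",)),
    ("dpta", ("pta",)),
    ("dfum+dpfl", ("fum", "pfl")),
    ("dgnd+dack", ("gnd", "ack")),
    ("dgdh+dpta", ("gdh", "pta")),
    ("dgdh+dack", ("gdh", "ack")),
    ("dgdh+dpfl", ("gdh", "pfl")),
    ("dmthfd+dack", ("mthfd", "ack")),
    ("dcbm+dack", ("cbm", "ack")),
]

_INSERTIONS = [("R00845", R00845), ("R01058", R01058)]

_COMBINED = [
    ("R01058+dack", R01058, ("ack",)),
    ("R01058+dpfl", R01058, ("pfl",)),
    ("R00845+dack", R00845, ("ack",)),
    ("R00845+dpfl", R00845, ("pfl",)),
]


def catalogue() -> list[GeneticStrategy]:
    """The sixteen studied strategies: 10 bacterial deletion sets, 2 yeast
    insertions, 4 insertion+deletion pairs."""
    out = [GeneticStrategy(name, "bacterium", deletions=dels)
           for name, dels in _DELETIONS]
    out += [GeneticStrategy(name, "yeast", insertions=(spec,))
            for name, spec in _INSERTIONS]
    out += [GeneticStrategy(name, "both", deletions=dels, insertions=(spec,))
            for name, spec, dels in _COMBINED]
    return out


# -- YAML round-trip --------------------------------------------------------

def strategy_to_yaml(strategy: GeneticStrategy) -> str:
    doc = {
        "name": strategy.name,
        "target_species": strategy.target_species,
        "deletions": list(strategy.deletions),
        "insertions": [{
            "id": s.id, "name": s.name, "reversible": s.reversible,
            "compartment": s.compartment,
            "stoichiometry": dict(s.stoichiometry),
        } for s in strategy.insertions],
    }
    return yaml.safe_dump(doc, sort_keys=True)


def strategy_from_yaml(text: str) -> GeneticStrategy:
    doc = yaml.safe_load(text)
    return GeneticStrategy(
        name=doc["name"],
        target_species=doc["target_species"],
        deletions=tuple(doc.get("deletions", ())),
        insertions=tuple(
            ReactionSpec(id=s["id"], stoichiometry=s["stoichiometry"],
                         reversible=s["reversible"],
                         compartment=s.get("compartment", "c"),
                         name=s.get("name", ""))
            for s in doc.get("insertions", ())),
    )


# -- application and scan ---------------------------------------------------

def apply_strategy(strategy: GeneticStrategy, yeast: SpeciesSpec,
                   bacterium: SpeciesSpec,
                   alias_map: Mapping[str, Sequence[str]] | None = None,
                   ) -> tuple[SpeciesSpec, SpeciesSpec]:
    """Return edited copies of the species per the strategy's target."""
    alias_map = alias_map or load_alias_map()
    y_model, b_model = yeast.model, bacterium.model
    if strategy.target_species in ("bacterium", "both"):
        b_model = apply_deletions(b_model, strategy.deletions, alias_map)
    if strategy.target_species == "yeast" and strategy.deletions:
        y_model = apply_deletions(y_model, strategy.deletions, alias_map)
    if strategy.target_species in ("yeast", "both"):
        for spec in strategy.insertions:
            y_model = apply_insertion(y_model, spec)
    return yeast.with_model(y_model), bacterium.with_model(b_model)


def run_scan(yeast: SpeciesSpec, bacterium: SpeciesSpec,
             strategies: Sequence[GeneticStrategy],
             mixtures: Sequence[cfg.Mixture] = cfg.MIXTURES,
             alias_map: Mapping[str, Sequence[str]] | None = None,
             conf_template: SimulationConfig | None = None,
             optimize: bool = True,
             switch_tol: float = 0.05,
             grid_points: int = 8,
             ) -> pd.DataFrame:
    """Evaluate the base case plus every strategy on every sugar mixture.

    Per row: edit the models, re-optimize the switching time (t_f is held at
    the mixture's horizon), simulate at the optimum, summarize. Rows come out
    in deterministic order (mixtures outer, base case first); a failing row
    records its error and the scan continues. Row count is
    ``len(mixtures) * (len(strategies) + 1)``.
    """
    alias_map = alias_map or load_alias_map()
    rows = []
    for mixture in mixtures:
        if conf_template is not None:
            conf = replace(conf_template, t_f=mixture.t_f,
                           t_s=min(conf_template.t_s, mixture.t_f),
                           glucose_0=mixture.glucose_0,
                           xylose_0=mixture.xylose_0)
        else:
            conf = SimulationConfig(
                t_f=mixture.t_f, t_s=mixture.t_f / 2.0,
                glucose_0=mixture.glucose_0, xylose_0=mixture.xylose_0)
        for strategy in [None, *strategies]:
            label = strategy.name if strategy else "base"
            row = {"strategy": label, "mixture": mixture.name,
                   "glucose_0": mixture.glucose_0, "xylose_0": mixture.xylose_0,
                   "t_f": mixture.t_f, "error": ""}
            try:
                y, b = (apply_strategy(strategy, yeast, bacterium, alias_map)
                        if strategy else (yeast, bacterium))
                if optimize:
                    sw = optimize_switch(conf, y, b, tol=switch_tol,
                                         grid_points=grid_points)
                    conf_run = replace(conf, t_s=sw.t_s_opt)
                    row["t_s"] = sw.t_s_opt
                    row["switch_evaluations"] = sw.evaluations
                else:
                    conf_run = conf
                    row["t_s"] = conf.t_s
                traj = simulate_batch(conf_run, y, b, record_fluxes=False)
                m = summarize(traj)
                row.update({
                    "ethanol_g": m.ethanol_total,
                    f"ethanol_{yeast.name}_g": m.ethanol_per_species[yeast.name],
                    f"ethanol_{bacterium.name}_g": m.ethanol_per_species[bacterium.name],
                    "yield_g_per_g": m.yield_eth,
                    "productivity_g_per_h": m.productivity,
                    "glucose_final": m.glucose_final,
                    "xylose_final": m.xylose_final,
                })
                for (species, compound), grams in sorted(m.byproducts.items()):
                    row[f"{compound}_{species}_g"] = grams
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
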