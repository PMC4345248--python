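"""Small carbon-balanced toy metabolic networks with known optima.

Every other module is exercised against these generators, so the whole
pipeline runs without downloading any genome-scale model. Two species kinds
are emitted:

* ``yeast_like`` — grows on glucose only; a fermentation branch
  (glucose -> 2 ethanol + 2 CO2, 2 ATP), a respiration branch
  (glucose + 6 O2 -> 6 CO2, high ATP), and a biomass reaction that
  co-produces glycerol. Aerobic biomass yield exceeds the anaerobic one, so
  an aerobic phase grows cells fast and an anaerobic phase makes ethanol.
* ``bacterium_like`` — grows on xylose only; its fermentation branches are
  the NADH-balanced elementary modes of a lumped mixed-acid network:
  a pyruvate-formate-lyase (PFL) dependent mode producing
  ethanol + acetate + formate with the highest anaerobic ATP yield, a
  PFL-independent all-ethanol mode (lower ATP), and an optional
  succinate branch. Deleting the PFL mode therefore zeroes formate and
  strictly increases optimal ethanol while lowering growth — the knockout
  phenotype the genome-scale scan looks for.

ATP is an abstract energy currency (no elemental formula); every other
metabolite carries a formula, and each non-exchange reaction is carbon
balanced by construction. The toy biomass unit is one carbon-equivalent of
25 g/mol, so unit conversions downstream are exercised nontrivially.

Alongside each model the generator returns a :class:`ToyOracle` whose
closed-form optimum (a one-dimensional energy-allocation argument, solved
segment by segment) and the exhaustive :func:`enumerate_vertices` oracle are
independent of the LP solver they are used to check.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fba_core import apply_uptake_caps
from .model_io import MetabolicModel

__all__ = [
    "ToySpec", "ToyOracle", "AnalyticOptimum", "Mode",
    "yeast_toy_spec", "bacterium_toy_spec", "make_toy_model",
    "enumerate_vertices", "oracle_lexicographic", "random_toy_spec",
    "toy_coculture", "exchange_map", "CARBON", "FORMULAS", "carbon_count",
]

BOUND = 1000.0

FORMULAS = {
    "glc": "C6H12O6", "xyl": "C5H10O5", "etoh": "C2H6O", "glyc": "C3H8O3",
    "ac": "C2H4O2", "for": "CH2O2", "lac": "C3H6O3", "succ": "C4H6O4",
    "co2": "CO2", "o2": "O2", "biomass": "C",
}

_MET_BY_PRODUCT = {
    "ethanol": "etoh", "glycerol": "glyc", "acetate": "ac", "formate": "for",
    "lactate": "lac", "succinate": "succ", "co2": "co2",
}

#: carbon atoms per metabolite (derived from FORMULAS; ATP is carbon-free
#: pseudo-currency by construction)
def carbon_count(formula: str) -> int:
    m = re.search(r"C(?![a-z])(\d*)", formula or "")
    if not m:
        return 0
    return int(m.group(1) or 1)


CARBON = {met: carbon_count(f) for met, f in FORMULAS.items()}
CARBON["atp"] = 0


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy species.

    Yields are in gDW per mmol sugar; ``product_branches`` gives the
    per-mmol-sugar stoichiometry of the species' characteristic products
    (the generator fills the remaining carbon with CO2 and errors if the
    branches overdraw the substrate carbon). ``maintenance`` is a lower
    bound on the ATP-hydrolysis flux (mmol ATP/gDW/h). ``degenerate`` adds
    an ethanol-poor fermentation mode with identical ATP yield, so the
    growth optimum becomes a face with vertices of different ethanol.
    """

    species_kind: str                      # "yeast_like" | "bacterium_like"
    sugar: str                             # "glucose" | "xylose"
    biomass_yield_aerobic: float
    biomass_yield_anaerobic: float
    product_branches: tuple[tuple[str, float], ...]
    maintenance: float = 0.0
    degenerate: bool = False

    def branch(self, product: str, default: float = 0.0) -> float:
        for name, val in self.product_branches:
            if name == product:
                return val
        return default

    def has_branch(self, product: str) -> bool:
        return any(name == product for name, _ in self.product_branches)


def yeast_toy_spec(**overrides) -> ToySpec:
    """Default glucose-only species: ~0.5 g/g aerobic and ~0.1 g/g anaerobic
    cellmass yield, 2 ethanol per glucose fermented, 0.3 glycerol per glucose
    routed to biomass."""
    kw = dict(
        species_kind="yeast_like", sugar="glucose",
        biomass_yield_aerobic=0.090, biomass_yield_anaerobic=0.018,
        product_branches=(("ethanol", 2.0), ("glycerol", 0.3)),
        maintenance=0.0, degenerate=False,
    )
    kw.update(overrides)
    return ToySpec(**kw)


def bacterium_toy_spec(**overrides) -> ToySpec:
    """Default xylose-only species with the mixed-acid fermentation profile
    (5/6 ethanol + 5/6 acetate + 5/3 formate per xylose) plus a minor
    succinate branch. Biomass yields are typical facultative-anaerobe values
    (~0.51 g/g aerobic, ~0.10 g/g anaerobic): with the standard
    20 mmol/gDW/h oxygen cap this puts oxygen-limited aerobic growth near
    0.82 1/h and anaerobic growth near 0.18 1/h, so the organism builds a
    few g/L of cells during a 7-8 h aerobic phase and finishes its sugar
    anaerobically - the regime the substrate-selective coculture operates
    in."""
    kw = dict(
        species_kind="bacterium_like", sugar="xylose",
        biomass_yield_aerobic=0.077, biomass_yield_anaerobic=0.015,
        product_branches=(("ethanol", 5.0 / 6.0), ("acetate", 5.0 / 6.0),
                          ("formate", 5.0 / 3.0), ("succinate", 1.0)),
        maintenance=0.0, degenerate=False,
    )
    kw.update(overrides)
    return ToySpec(**kw)


@dataclass(frozen=True)
class Mode:
    """One sugar-consuming pathway: ATP and product yields per mmol sugar."""

    name: str
    atp: float
    o2: float                              # mmol O2 consumed per mmol sugar
    products: dict[str, float]             # metabolite id -> mol per mol sugar

    @property
    def ethanol(self) -> float:
        return self.products.get("etoh", 0.0)


@dataclass
class AnalyticOptimum:
    status: str                            # "optimal" | "infeasible"
    mu: float = 0.0
    biomass_flux: float = 0.0              # mmol sugar to biomass /gDW/h
    ethanol: float = 0.0                   # stage-2 ethanol secretion flux
    stage1_ethanol_range: tuple[float, float] = (0.0, 0.0)
    mode_fluxes: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)


@dataclass
class ToyOracle:
    """Closed-form two-stage optimum of a generated toy model."""

    species_kind: str
    sugar_met: str
    modes: list[Mode]
    atp_per_biomass: float                 # a: mmol ATP per mmol sugar to biomass
    biomass_units: float                   # n_b: biomass carbon-equivalents per sugar
    biomass_products: dict[str, float]     # growth-coupled co-products per sugar
    maintenance: float

    @property
    def yield_max(self) -> float:
        """Carbon-limited ceiling on biomass yield, gDW/mmol sugar."""
        return 0.025 * self.biomass_units

    def analytic_optimum(self, sugar_cap: float, o2_cap: float) -> AnalyticOptimum:
        """Two-stage optimum under uptake caps, by energy allocation.

        Growth costs ``a`` ATP per mmol sugar built into cells; energy comes
        from respiration (best ATP per sugar, O2-capped) then the best
        fermentation mode. Maximal growth solves
        ``a*x + m = ATP(S - x)`` with ``ATP`` piecewise linear, segment by
        segment. At that optimum the ATP constraint is tight, so stage 2 can
        only re-split flux among fermentation modes of equal ATP yield and
        picks the ethanol-richest one.
        """
        m = self.maintenance
        a = self.atp_per_biomass
        S = float(sugar_cap)
        ferm = [md for md in self.modes if md.o2 == 0.0]
        resp = [md for md in self.modes if md.o2 > 0.0]
        p_max = max((md.atp for md in ferm), default=0.0)
        tied = [md for md in ferm if abs(md.atp - p_max) <= 1e-12]
        best = max(tied, key=lambda md: md.ethanol) if tied else None
        r_mode = resp[0] if resp else None
        r_max = min(S, o2_cap / r_mode.o2) if r_mode else 0.0
        q = r_mode.atp if r_mode else 0.0

        atp_max = q * r_max + p_max * max(S - r_max, 0.0)
        if atp_max < m - 1e-12:
            return AnalyticOptimum(status="infeasible")

        x = r = f = None
        if r_mode is not None and q > 0:
            # segment 1: respiration alone funds growth (O2 not binding)
            x1 = (q * S - m) / (q + a)
            F1 = S - x1
            if x1 >= -1e-12 and 0.0 <= F1 <= r_max + 1e-12:
                x, r, f = max(x1, 0.0), min(F1, r_max), 0.0
        if x is None:
            # segment 2: O2 cap saturated, best fermentation tops up ATP
            r2 = r_max
            if p_max + a <= 0:
                return AnalyticOptimum(status="infeasible")
            x2 = (p_max * (S - r2) + q * r2 - m) / (p_max + a)
            if x2 < 0.0:
                x2 = 0.0  # maintenance consumes all energy; no growth
            f2 = S - r2 - x2
            if f2 < -1e-9:
                return AnalyticOptimum(status="infeasible")
            x, r, f = x2, r2, max(f2, 0.0)

        mode_fluxes = {}
        if r_mode is not None and r > 0:
            mode_fluxes[r_mode.name] = r
        if best is not None and f > 0:
            mode_fluxes[best.name] = f
        products: dict[str, float] = {}
        for md in self.modes:
            fl = mode_fluxes.get(md.name, 0.0)
            for met, coef in md.products.items():
                products[met] = products.get(met, 0.0) + coef * fl
        for met, coef in self.biomass_products.items():
            products[met] = products.get(met, 0.0) + coef * x
        eth = best.ethanol * f if best is not None else 0.0
        eth_range = (min(md.ethanol for md in tied) * f, eth) if tied else (0.0, 0.0)
        return AnalyticOptimum(
            status="optimal",
            mu=0.025 * self.biomass_units * x,
            biomass_flux=x,
            ethanol=eth,
            stage1_ethanol_range=eth_range,
            mode_fluxes=mode_fluxes,
            products=products,
        )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _assemble(name: str, sugar_met: str, modes: list[Mode], a: float,
              n_b: float, biomass_products: dict[str, float],
              maintenance: float, include_o2: bool) -> MetabolicModel:
    mets = [sugar_met, "atp", "biomass"]
    if include_o2:
        mets.append("o2")
    product_mets = sorted({m for md in modes for m in md.products}
                          | set(biomass_products))
    mets += [m for m in product_mets if m not in mets]

    reactions: list[tuple[str, dict[str, float], float, float, float]] = []
    for md in modes:
        stoich = {sugar_met: -1.0, **{k: v for k, v in md.products.items()}}
        if md.atp:
            stoich["atp"] = stoich.get("atp", 0.0) + md.atp
        if md.o2:
            stoich["o2"] = -md.o2
        reactions.append((md.name, stoich, 0.0, BOUND, 0.0))
    bio_stoich = {sugar_met: -1.0, "atp": -a, "biomass": n_b}
    for met, coef in biomass_products.items():
        bio_stoich[met] = bio_stoich.get(met, 0.0) + coef
    reactions.append(("BIOMASS", bio_stoich, 0.0, BOUND, 0.025 * n_b))
    reactions.append(("ATPM", {"atp": -1.0}, maintenance, BOUND, 0.0))

    # ATPM drains ATP across the boundary, so it is structurally an
    # exchange (and round-trips through SBML/JSON as one)
    exchange_ids = ["ATPM"]
    for met in mets:
        if met == "atp":
            continue
        rid = f"EX_{met}"
        # substrates enter via caps set at solve time; products secrete only
        lb = 0.0
        reactions.append((rid, {met: -1.0}, lb, BOUND, 0.0))
        exchange_ids.append(rid)

    met_pos = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    rxn_ids, lbs, ubs, ws = [], [], [], []
    for j, (rid, stoich, lo, hi, w) in enumerate(reactions):
        rxn_ids.append(rid)
        lbs.append(lo)
        ubs.append(hi)
        ws.append(w)
        for met, coef in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(coef)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(reactions)))
    return MetabolicModel(
        metabolite_ids=mets, reaction_ids=rxn_ids, stoichiometry=A,
        lower_bounds=np.array(lbs), upper_bounds=np.array(ubs),
        objective_weights=np.array(ws), exchange_ids=exchange_ids, name=name,
        metabolite_formulas={m: FORMULAS[m] for m in mets if m in FORMULAS},
    )


def _check_carbon(sugar_carbon: float, products: dict[str, float], where: str) -> float:
    used = sum(CARBON[m] * c for m, c in products.items())
    co2_fill = sugar_carbon - used
    if co2_fill < -1e-9:
        raise ValueError(
            f"{where}: product branches carry {used} carbons,"
            f" exceeding the {sugar_carbon} of the substrate")
    return co2_fill


def make_toy_model(spec: ToySpec) -> tuple[MetabolicModel, ToyOracle]:
    """Build a toy model and its closed-form optimum record.

    Emits at most 15 reactions; the non-degenerate variants stay within the
    12-column bound of :func:`enumerate_vertices`. Raises ``ValueError`` for
    carbon-overdrawn branches or inconsistent yields.
    """
    if spec.biomass_yield_anaerobic <= 0 or spec.biomass_yield_aerobic <= 0:
        raise ValueError("biomass yields must be positive")
    if spec.biomass_yield_aerobic < spec.biomass_yield_anaerobic:
        raise ValueError("aerobic biomass yield must be >= anaerobic")

    if spec.species_kind == "yeast_like":
        if spec.sugar != "glucose":
            raise ValueError("yeast_like species grows on glucose")
        sugar_met, sugar_c = "glc", 6.0
        e = spec.branch("ethanol", 2.0)
        g = spec.branch("glycerol", 0.0)
        co2_f = _check_carbon(sugar_c, {"etoh": e}, "fermentation branch")
        # biomass units = sugar carbons not routed to glycerol
        n_b = _check_carbon(sugar_c, {"glyc": g}, "biomass branch")
        if n_b <= 0:
            raise ValueError("glycerol branch consumes all substrate carbon")
        p_ferm = 2.0
        modes = [Mode("FERM", atp=p_ferm, o2=0.0,
                      products={"etoh": e, "co2": co2_f})]
        if spec.degenerate:
            modes.append(Mode("FERM_ALT", atp=p_ferm, o2=0.0,
                              products={"etoh": e / 2.0, "co2": co2_f + e}))
        biomass_products = {"glyc": g} if g else {}
        o2_per_sugar = 6.0
    elif spec.species_kind == "bacterium_like":
        if spec.sugar != "xylose":
            raise ValueError("bacterium_like species grows on xylose")
        sugar_met, sugar_c = "xyl", 5.0
        e = spec.branch("ethanol", 5.0 / 6.0)
        c_ac = spec.branch("acetate", 5.0 / 6.0)
        f_for = spec.branch("formate", 5.0 / 3.0)
        if c_ac <= 0:
            raise ValueError(
                "bacterium_like needs an acetate branch: acetate kinase is"
                " the extra substrate-level ATP that makes the mixed-acid"
                " mode the anaerobic growth optimum")
        co2_m = _check_carbon(sugar_c, {"etoh": e, "ac": c_ac, "for": f_for},
                              "mixed-acid branch")
        p_mix = 2.0 + c_ac          # glycolytic ATP + acetate-kinase ATP
        p_eth = 2.0                 # PFL-independent all-ethanol mode
        modes = [
            Mode("FERM_MIX", atp=p_mix, o2=0.0,
                 products={"etoh": e, "ac": c_ac, "for": f_for, "co2": co2_m}),
            Mode("FERM_ETH", atp=p_eth, o2=0.0,
                 products={"etoh": 5.0 / 3.0, "co2": 5.0 / 3.0}),
        ]
        if spec.degenerate:
            modes.append(Mode("FERM_MIX_ALT", atp=p_mix, o2=0.0,
                              products={"etoh": e / 2.0, "ac": c_ac,
                                        "for": f_for, "co2": co2_m + e}))
        if spec.has_branch("succinate"):
            s = spec.branch("succinate")
            co2_s = _check_carbon(sugar_c, {"succ": s, "for": 1.0}, "succinate branch")
            modes.append(Mode("FERM_SUC", atp=1.0, o2=0.0,
                              products={"succ": s, "for": 1.0, "co2": co2_s}))
        n_b = sugar_c
        biomass_products = {}
        o2_per_sugar = 5.0
    else:
        raise ValueError(f"unknown species kind {spec.species_kind!r}")

    y_max = 0.025 * n_b
    if spec.biomass_yield_aerobic >= y_max:
        raise ValueError(
            f"aerobic yield {spec.biomass_yield_aerobic} g/mmol exceeds the"
            f" carbon ceiling {y_max:.4f} g/mmol")
    p_best = max(md.atp for md in modes if md.o2 == 0.0)
    a = p_best * (y_max - spec.biomass_yield_anaerobic) / spec.biomass_yield_anaerobic
    q = a * spec.biomass_yield_aerobic / (y_max - spec.biomass_yield_aerobic)

    # degenerate bacterium toys omit respiration to stay within the
    # 12-column vertex-enumeration bound; degeneracy checks are anaerobic
    include_resp = not (spec.degenerate and spec.species_kind == "bacterium_like")
    if include_resp:
        modes = modes + [Mode("RESP", atp=q, o2=o2_per_sugar,
                              products={"co2": sugar_c})]

    model = _assemble(f"toy_{spec.species_kind}", sugar_met, modes, a, n_b,
                      biomass_products, spec.maintenance,
                      include_o2=include_resp)
    oracle = ToyOracle(
        species_kind=spec.species_kind, sugar_met=sugar_met, modes=modes,
        atp_per_biomass=a, biomass_units=n_b,
        biomass_products=biomass_products, maintenance=spec.maintenance,
    )
    return model, oracle


# ---------------------------------------------------------------------------
# exhaustive vertex enumeration (LP test oracle)
# ---------------------------------------------------------------------------

def enumerate_vertices(model: MetabolicModel,
                       uptake_caps: dict[str, float] | None = None,
                       objective_fix: tuple[np.ndarray, float] | None = None,
                       max_reactions: int = 12,
                       ) -> list[tuple[np.ndarray, float]]:
    """All basic feasible points of ``{A v = 0, bounds}`` with objectives.

    Vertices are found by fixing ``n - rank(A)`` fluxes at finite bounds and
    solving the remaining square-rank system; every candidate is verified
    against the full constraint set. ``objective_fix=(w, value)`` appends the
    equality ``w @ v = value`` (used to enumerate the stage-2 optimal face).
    Combinatorial, hence restricted to ``max_reactions`` columns.
    """
    n = model.n_reactions
    if n > max_reactions:
        raise ValueError(
            f"model has {n} reactions > {max_reactions}; use the LP solver"
            " for networks this size")
    lb, ub = apply_uptake_caps(model, uptake_caps or {})
    A = model.stoichiometry.toarray()
    b = np.zeros(A.shape[0])
    if objective_fix is not None:
        w, value = objective_fix
        A = np.vstack([A, np.asarray(w, dtype=float)])
        b = np.append(b, value)
    rank = np.linalg.matrix_rank(A)
    k = n - rank

    seen: dict[tuple, tuple[np.ndarray, float]] = {}
    w_obj = model.objective_weights

    def record(v: np.ndarray) -> None:
        if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
            return
        if np.max(np.abs(A @ v - b)) > 1e-8 * max(1.0, np.abs(b).max()):
            return
        key = tuple(np.round(v, 6))
        if key not in seen:
            seen[key] = (v.copy(), float(w_obj @ v))

    if k == 0:
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        record(v)
        return list(seen.values())

    cols = range(n)
    for fixed in itertools.combinations(cols, k):
        free = [j for j in cols if j not in fixed]
        A_free = A[:, free]
        if np.linalg.matrix_rank(A_free) < len(free):
            continue
        choices = []
        for j in fixed:
            opts = []
            if np.isfinite(lb[j]):
                opts.append(lb[j])
            if np.isfinite(ub[j]) and ub[j] != lb[j]:
                opts.append(ub[j])
            if not opts:
                break
            choices.append(opts)
        if len(choices) < k:
            continue
        for vals in itertools.product(*choices):
            rhs = b - A[:, fixed] @ np.asarray(vals)
            v_free, residual, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            v = np.empty(n)
            v[free] = v_free
            v[list(fixed)] = vals
            record(v)
    return list(seen.values())


def oracle_lexicographic(model: MetabolicModel, uptake_caps: dict[str, float],
                         ethanol_id: str, tol: float = 1e-9,
                         ) -> tuple[float, float]:
    """Two-stage optimum by brute force: (max growth, max ethanol at it)."""
    verts = enumerate_vertices(model, uptake_caps)
    if not verts:
        raise RuntimeError("no feasible vertex: problem infeasible")
    mu_star = max(obj for _, obj in verts)
    face = enumerate_vertices(model, uptake_caps,
                              objective_fix=(model.objective_weights, mu_star))
    j = model.reaction_index(ethanol_id)
    eth_star = max(v[j] for v, _ in face)
    return mu_star, eth_star


# ---------------------------------------------------------------------------
# randomized specs (seeded) for solver-vs-oracle sweeps
# ---------------------------------------------------------------------------

_EXCHANGE_NAMES = {
    "glucose": "EX_glc", "xylose": "EX_xyl", "oxygen": "EX_o2",
    "ethanol": "EX_etoh", "glycerol": "EX_glyc", "acetate": "EX_ac",
    "formate": "EX_for", "lactate": "EX_lac", "succinate": "EX_succ",
    "co2": "EX_co2", "biomass": "EX_biomass",
}


def exchange_map(model: MetabolicModel) -> dict[str, str]:
    """Compound-name -> exchange-id map for a toy model (present ids only)."""
    return {name: rid for name, rid in _EXCHANGE_NAMES.items()
            if rid in set(model.exchange_ids)}


def toy_coculture(yeast_spec: ToySpec | None = None,
                  bacterium_spec: ToySpec | None = None):
    """Species pair under the standard operating conditions, plus oracles.

    Returns ``(yeast, bacterium, {"SC": oracle, "EC": oracle})`` where the
    species carry the default coculture uptake kinetics.
    """
    from . import config
    from .dynamics import SpeciesSpec

    y_model, y_oracle = make_toy_model(yeast_spec or yeast_toy_spec())
    b_model, b_oracle = make_toy_model(bacterium_spec or bacterium_toy_spec())
    yeast = SpeciesSpec("SC", y_model, config.YEAST_KINETICS,
                        exchanges=exchange_map(y_model))
    bacterium = SpeciesSpec("EC", b_model, config.BACTERIUM_KINETICS,
                            exchanges=exchange_map(b_model))
    return yeast, bacterium, {"SC": y_oracle, "EC": b_oracle}


def random_toy_spec(rng: np.random.Generator) -> ToySpec:
    """Sample a valid ToySpec; emitted models stay within 12 reactions."""
    degenerate = bool(rng.random() < 0.3)
    maintenance = float(rng.uniform(0.0, 2.0)) if rng.random() < 0.5 else 0.0
    if rng.random() < 0.5:
        g = float(rng.uniform(0.0, 0.5))
        e = float(rng.uniform(1.0, 2.5))
        y_max = 0.025 * (6.0 - 3.0 * g)
        u1 = rng.uniform(0.05, 0.6)
        u2 = rng.uniform(u1 + 0.05, 0.92)
        return ToySpec(
            species_kind="yeast_like", sugar="glucose",
            biomass_yield_aerobic=float(y_max * u2),
            biomass_yield_anaerobic=float(y_max * u1),
            product_branches=(("ethanol", e), ("glycerol", g)),
            maintenance=maintenance, degenerate=degenerate,
        )
    e = float(rng.uniform(0.2, 0.9))
    c = float(rng.uniform(0.2, min(0.9, 5.0 / 3.0 - e - 0.05)))
    f = e + c  # one formate per PFL-cleaved pyruvate
    y_max = 0.125
    u1 = rng.uniform(0.03, 0.5)
    u2 = rng.uniform(u1 + 0.05, 0.9)
    return ToySpec(
        species_kind="bacterium_like", sugar="xylose",
        biomass_yield_aerobic=float(y_max * u2),
        biomass_yield_anaerobic=float(y_max * u1),
        product_branches=(("ethanol", e), ("acetate", c), ("formate", f)),
        maintenance=maintenance, degenerate=degenerate,
    )
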