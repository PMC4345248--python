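"""Instantaneous flux balance problems, single species and coculture.

The primal problem maximizes growth ``w @ v`` subject to steady state
``A v = 0`` and flux bounds. Because the growth LP is typically degenerate,
the secondary (lexicographic) stage fixes growth at its optimum and
re-maximizes the ethanol secretion flux, which is the quantity that feeds
the extracellular mass balances. All solves go through scipy's HiGHS
implementation, which is deterministic for a fixed model and bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "FluxSolution",
    "solve_growth",
    "solve_lexicographic",
    "solve_coculture",
    "variability_at_optimum",
    "TwoStageLP",
]

#: Relative relaxation applied when fixing stage-1 growth in stage 2. Only
#: solver round-off needs absorbing (the stage-1 optimum is a basic solution
#: of the same problem), and any slack here is traded into spurious ethanol
#: at a steep exchange ratio, so it is kept near machine precision. If the
#: relaxed stage 2 still comes back infeasible, the solvers fall back to the
#: stage-1 vertex.
EPS_FIX = 1e-12


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``mu`` is the growth rate ``w @ v`` (1/h); ``fluxes`` are per-reaction
    values aligned with the model's reaction ids (mmol/gDW/h); ``exchanges``
    holds named exchange fluxes (negative = uptake). ``stage1_mu`` records
    the growth optimum before the ethanol stage for lexicographic solves.
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    mu: float = 0.0
    fluxes: np.ndarray | None = None
    reaction_ids: list[str] = field(default_factory=list)
    exchanges: dict[str, float] = field(default_factory=dict)
    stage1_mu: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(reaction_id)])


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


def apply_uptake_caps(model: MetabolicModel,
                      uptake_caps: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Bounds with each capped exchange's lower bound set to ``-cap``.

    Caps must be non-negative and name exchange reactions.
    """
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    exchange = set(model.exchange_ids)
    for rid, cap in uptake_caps.items():
        if rid not in exchange:
            raise ValueError(f"uptake cap on non-exchange reaction {rid!r}")
        if cap < 0:
            raise ValueError(f"negative uptake cap for {rid!r}: {cap}")
        lb[model.reaction_index(rid)] = -cap
    return lb, ub


def _solve_lp(model: MetabolicModel, c: np.ndarray, lb: np.ndarray,
              ub: np.ndarray, extra_ub: tuple[np.ndarray, float] | None = None):
    A_eq = model.stoichiometry
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub = sp.csr_matrix(extra_ub[0].reshape(1, -1))
        b_ub = [extra_ub[1]]
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                   bounds=np.column_stack([lb, ub]), method="highs")


def _named_exchanges(model: MetabolicModel, fluxes: np.ndarray,
                     exchange_map: Mapping[str, str] | None) -> dict[str, float]:
    if not exchange_map:
        return {}
    out = {}
    for name, rid in exchange_map.items():
        if rid in model._rxn_index:
            out[name] = float(fluxes[model.reaction_index(rid)])
    return out


def solve_growth(model: MetabolicModel, uptake_caps: Mapping[str, float],
                 exchange_map: Mapping[str, str] | None = None) -> FluxSolution:
    """Maximize growth subject to ``A v = 0`` and capped uptake bounds.

    Returns ``status="infeasible"`` (rather than raising) when no feasible
    flux vector exists, e.g. unmet ATP maintenance with all caps at zero.
    """
    lb, ub = apply_uptake_caps(model, uptake_caps)
    res = _solve_lp(model, -model.objective_weights, lb, ub)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, reaction_ids=list(model.reaction_ids))
    v = res.x
    return FluxSolution(
        status="optimal",
        mu=float(model.objective_weights @ v),
        fluxes=v,
        reaction_ids=list(model.reaction_ids),
        exchanges=_named_exchanges(model, v, exchange_map),
    )


def solve_lexicographic(model: MetabolicModel, uptake_caps: Mapping[str, float],
                        ethanol_id: str,
                        exchange_map: Mapping[str, str] | None = None,
                        ) -> FluxSolution:
    """Two-stage solve: maximize growth, fix it, then maximize ethanol.

    Stage 2 keeps growth within ``EPS_FIX * max(1, |mu*|)`` of the stage-1
    optimum and selects, among the alternate growth optima, the flux vector
    with maximal ethanol secretion.
    """
    stage1 = solve_growth(model, uptake_caps, exchange_map)
    if not stage1.optimal:
        return stage1
    mu_star = stage1.mu
    lb, ub = apply_uptake_caps(model, uptake_caps)
    j_eth = model.reaction_index(ethanol_id)
    c = np.zeros(model.n_reactions)
    c[j_eth] = -1.0
    slack = EPS_FIX * max(1.0, abs(mu_star))
    # w @ v >= mu* - slack  <=>  -w @ v <= -(mu* - slack)
    res = _solve_lp(model, c, lb, ub,
                    extra_ub=(-model.objective_weights, -(mu_star - slack)))
    if _STATUS.get(res.status, "numerical") != "optimal":
        # stage 2 cannot be worse-posed than stage 1; treat as degenerate
        # numerical failure and fall back to the stage-1 vertex
        stage1.stage1_mu = mu_star
        return stage1
    v = res.x
    return FluxSolution(
        status="optimal",
        mu=float(model.objective_weights @ v),
        fluxes=v,
        reaction_ids=list(model.reaction_ids),
        exchanges=_named_exchanges(model, v, exchange_map),
        stage1_mu=mu_star,
    )


def solve_coculture(models: Sequence[MetabolicModel],
                    uptake_caps: Sequence[Mapping[str, float]],
                    ethanol_ids: Sequence[str] | None = None,
                    exchange_maps: Sequence[Mapping[str, str] | None] | None = None,
                    ) -> tuple[FluxSolution, FluxSolution]:
    """Solve the block-diagonal two-species growth LP.

    The joint stage-1 problem maximizes ``mu_SC + mu_EC`` over the
    block-diagonal constraint matrix; because the blocks share no variables
    this equals two independent solves, and each block attains its own
    optimum at the joint optimum. Stage 2 (per-species ethanol) is then run
    per block. Provided for fidelity to the coculture formulation and used
    as a cross-check of the independent path.
    """
    if len(models) != 2 or len(uptake_caps) != 2:
        raise ValueError("expected exactly two species")
    exchange_maps = exchange_maps or (None, None)
    bounds = [apply_uptake_caps(m, c) for m, c in zip(models, uptake_caps)]
    A = sp.block_diag([m.stoichiometry for m in models], format="csc")
    w = np.concatenate([m.objective_weights for m in models])
    lb = np.concatenate([b[0] for b in bounds])
    ub = np.concatenate([b[1] for b in bounds])
    res = linprog(-w, A_eq=A, b_eq=np.zeros(A.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    joint_status = _STATUS.get(res.status, "numerical")

    out = []
    offset = 0
    for k, model in enumerate(models):
        n = model.n_reactions
        if joint_status == "optimal":
            if ethanol_ids is not None:
                sol = solve_lexicographic(model, uptake_caps[k], ethanol_ids[k],
                                          exchange_maps[k])
            else:
                v = res.x[offset:offset + n]
                sol = FluxSolution(
                    status="optimal",
                    mu=float(model.objective_weights @ v),
                    fluxes=v,
                    reaction_ids=list(model.reaction_ids),
                    exchanges=_named_exchanges(model, v, exchange_maps[k]),
                )
        else:
            # joint infeasibility is per-block: report each block on its own
            sol = (solve_lexicographic(model, uptake_caps[k], ethanol_ids[k],
                                       exchange_maps[k])
                   if ethanol_ids is not None
                   else solve_growth(model, uptake_caps[k], exchange_maps[k]))
        out.append(sol)
        offset += n
    return out[0], out[1]


class TwoStageLP:
    """Persistent lexicographic solver for repeated solves of one model.

    The dynamic simulation solves the same LP thousands of times with only
    the uptake bounds changing, so the problem is kept loaded in GLPK and
    re-solved from the previous basis (microseconds per solve instead of the
    per-call setup cost of a one-shot solver). One extra constraint row holds
    ``w @ v >= mu* - slack`` during the ethanol stage and is released
    afterwards. Results agree with :func:`solve_lexicographic` to solver
    tolerance; both are deterministic for a fixed model and bound sequence.
    """

    def __init__(self, model: MetabolicModel, ethanol_id: str,
                 exchange_map: Mapping[str, str] | None = None):
        import swiglpk as glp

        self._glp = glp
        self.model = model
        self.exchange_map = dict(exchange_map or {})
        self._j_eth = model.reaction_index(ethanol_id) + 1
        m, n = model.n_metabolites, model.n_reactions
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, m + 1)
        glp.glp_add_cols(lp, n)
        for i in range(m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_set_row_bnds(lp, m + 1, glp.GLP_FR, 0.0, 0.0)  # growth fix row
        for j in range(n):
            self._set_col(lp, j + 1, model.lower_bounds[j], model.upper_bounds[j])
        A = model.stoichiometry.tocoo()
        w = model.objective_weights
        w_nz = [(j, w[j]) for j in range(n) if w[j] != 0.0]
        nnz = A.nnz + len(w_nz)
        ia, ja, ar = glp.intArray(nnz + 1), glp.intArray(nnz + 1), glp.doubleArray(nnz + 1)
        for k, (i, j, v) in enumerate(zip(A.row, A.col, A.data), start=1):
            ia[k], ja[k], ar[k] = int(i) + 1, int(j) + 1, float(v)
        for k, (j, wj) in enumerate(w_nz, start=A.nnz + 1):
            ia[k], ja[k], ar[k] = m + 1, j + 1, float(wj)
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_ERR
        self._lp, self._parm, self._m, self._n = lp, parm, m, n

    def _set_col(self, lp, j1: int, lo: float, hi: float) -> None:
        glp = self._glp
        lo_f, hi_f = np.isfinite(lo), np.isfinite(hi)
        if lo_f and hi_f:
            kind = glp.GLP_FX if lo == hi else glp.GLP_DB
        elif lo_f:
            kind = glp.GLP_LO
        elif hi_f:
            kind = glp.GLP_UP
        else:
            kind = glp.GLP_FR
        glp.glp_set_col_bnds(lp, j1, kind, float(lo), float(hi))

    def _simplex(self) -> str:
        glp = self._glp
        ret = glp.glp_simplex(self._lp, self._parm)
        if ret != 0:  # stale basis after bound edits: rebuild and retry cold
            glp.glp_std_basis(self._lp)
            ret = glp.glp_simplex(self._lp, self._parm)
            if ret != 0:
                return "numerical"
        status = glp.glp_get_status(self._lp)
        return {glp.GLP_OPT: "optimal", glp.GLP_NOFEAS: "infeasible",
                glp.GLP_UNBND: "unbounded"}.get(status, "numerical")

    def solve(self, uptake_caps: Mapping[str, float]) -> FluxSolution:
        """Two-stage solve under the given uptake caps."""
        glp, lp, model = self._glp, self._lp, self.model
        exchange = set(model.exchange_ids)
        for rid, cap in uptake_caps.items():
            if rid not in exchange:
                raise ValueError(f"uptake cap on non-exchange reaction {rid!r}")
            if cap < 0:
                raise ValueError(f"negative uptake cap for {rid!r}: {cap}")
            j = model.reaction_index(rid)
            self._set_col(lp, j + 1, -cap, model.upper_bounds[j])
        # stage 1: growth
        w = model.objective_weights
        for j in range(self._n):
            glp.glp_set_obj_coef(lp, j + 1, float(w[j]))
        status = self._simplex()
        if status != "optimal":
            return FluxSolution(status=status, reaction_ids=list(model.reaction_ids))
        mu_star = glp.glp_get_obj_val(lp)
        # stage 2: ethanol at fixed growth
        slack = EPS_FIX * max(1.0, abs(mu_star))
        glp.glp_set_row_bnds(lp, self._m + 1, glp.GLP_LO, mu_star - slack, 0.0)
        for j in range(self._n):
            glp.glp_set_obj_coef(lp, j + 1, 0.0)
        glp.glp_set_obj_coef(lp, self._j_eth, 1.0)
        status2 = self._simplex()
        v = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(self._n)])
        glp.glp_set_row_bnds(lp, self._m + 1, glp.GLP_FR, 0.0, 0.0)
        if status2 != "optimal":  # fall back to the stage-1 vertex
            glp.glp_set_obj_coef(lp, self._j_eth, 0.0)
            for j in range(self._n):
                glp.glp_set_obj_coef(lp, j + 1, float(w[j]))
            self._simplex()
            v = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(self._n)])
        return FluxSolution(
            status="optimal",
            mu=float(w @ v),
            fluxes=v,
            reaction_ids=list(model.reaction_ids),
            exchanges=_named_exchanges(model, v, self.exchange_map),
            stage1_mu=float(mu_star),
        )

    def __del__(self):
        try:
            self._glp.glp_delete_prob(self._lp)
        except Exception:
            pass


def variability_at_optimum(model: MetabolicModel,
                           uptake_caps: Mapping[str, float],
                           ethanol_id: str | None = None,
                           reactions: Sequence[str] | None = None,
                           fix_ethanol: bool = False,
                           tol: float = 1e-6) -> dict[str, tuple[float, float]]:
    """Flux ranges at the growth (and optionally ethanol) optimum.

    Returns ``{reaction_id: (min, max)}``. A range wider than ``tol`` marks a
    degenerate (non-unique) flux: by-product reporting at such an optimum is
    solver-vertex dependent and should be treated as a set, not a value.
    """
    stage1 = solve_growth(model, uptake_caps)
    if not stage1.optimal:
        raise RuntimeError("growth LP infeasible; no optimum to examine")
    lb, ub = apply_uptake_caps(model, uptake_caps)
    rows = [-model.objective_weights]
    rhs = [-(stage1.mu - EPS_FIX * max(1.0, abs(stage1.mu)))]
    if fix_ethanol:
        if ethanol_id is None:
            raise ValueError("fix_ethanol requires ethanol_id")
        lex = solve_lexicographic(model, uptake_caps, ethanol_id)
        j = model.reaction_index(ethanol_id)
        row = np.zeros(model.n_reactions)
        row[j] = -1.0
        rows.append(row)
        rhs.append(-(lex.fluxes[j] - EPS_FIX * max(1.0, abs(lex.fluxes[j]))))
    A_ub = sp.csr_matrix(np.vstack(rows))
    reactions = list(reactions) if reactions is not None else list(model.reaction_ids)
    out = {}
    for rid in reactions:
        j = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        extremes = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res = linprog(c, A_ub=A_ub, b_ub=rhs, A_eq=model.stoichiometry,
                          b_eq=np.zeros(model.n_metabolites),
                          bounds=np.column_stack([lb, ub]), method="highs")
            if res.status != 0:
                raise RuntimeError(f"variability LP failed for {rid!r}")
            extremes.append(float(res.x[j]))
        out[rid] = (min(extremes), max(extremes))
    return out
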