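"""LP/QP simulation methods at reaction and gene level.

Reaction-level methods (FBA, pFBA, MOMA, linearMOMA, FVA) run on either a
:class:`~gprflux.model.MetabolicModel` or an extended model; gene-level
variants (gene-pFBA, gene-MOMA, gene-lMOMA, expression modulation, usage
FVA, essentiality) require the extended model because they address the
enzyme-usage variables ``u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model import MetabolicModel, ModelError
from .solver import LPResult, SolverCapabilityError, qp_capable, solve_lp, solve_qp
from .transform import ExtendedModel, FluxSolution, GeneLevelSolution

__all__ = [
    "SimulationResult",
    "fba",
    "pfba",
    "moma",
    "simulate_modulation",
    "fva",
    "gene_essentiality",
]

FEASIBILITY_TOL = 1e-6
ESSENTIALITY_TOL = 1e-6


@dataclass
class SimulationResult:
    status: str  # optimal | infeasible | unbounded | error
    solution: object | None = None  # FluxSolution | GeneLevelSolution
    objective_value: float | None = None
    diagnostics: dict | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def fluxes(self) -> dict:
        if isinstance(self.solution, GeneLevelSolution):
            return self.solution.sub_fluxes
        return self.solution.fluxes if self.solution else {}


# ---------------------------------------------------------------------------
# linear view of a model (plain or extended)
# ---------------------------------------------------------------------------


class LinearView:
    """Columns, bounds, equality matrix and growth expression of a model."""

    def __init__(self, m):
        if isinstance(m, ExtendedModel):
            self.ext: ExtendedModel | None = m
            model = m.base
        else:
            self.ext = None
            model = m
        self.model = model
        self.ids = list(model.reactions)
        self.index = {r: i for i, r in enumerate(self.ids)}
        mets = list(model.metabolites)
        midx = {mm: i for i, mm in enumerate(mets)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.ids):
            for met, coef in model.reactions[rid].stoichiometry.items():
                if model.metabolites[met].is_external:
                    continue  # boundary species are not balanced
                rows.append(midx[met])
                cols.append(j)
                vals.append(coef)
        self.A = sp.csr_matrix((vals, (rows, cols)),
                               shape=(len(mets), len(self.ids)))
        self.bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound)
                       for r in self.ids]
        self.growth_expr = self._growth_expression()

    def _growth_expression(self) -> dict:
        if self.ext is not None:
            obj = self.ext.objective
            if obj is None:
                return {}
            expr = {}
            for sub in self.ext.split_map[obj]:
                expr[self.index[sub.id]] = 1.0 if sub.direction == "fwd" else -1.0
            return expr
        if self.model.objective is None:
            return {}
        return {self.index[self.model.objective]: 1.0}

    def growth_vector(self) -> np.ndarray:
        c = np.zeros(len(self.ids))
        for j, coef in self.growth_expr.items():
            c[j] = coef
        return c

    def usage_columns(self) -> dict:
        if self.ext is None:
            return {}
        return {g: self.index[rid] for g, rid in self.ext.usage_reactions.items()}

    def solution_from(self, x: np.ndarray, objective: float | None):
        values = {rid: float(x[i]) for rid, i in self.index.items()}
        if self.ext is None:
            return FluxSolution(fluxes=values, objective_value=objective)
        usage = {g: values[rid] for g, rid in self.ext.usage_reactions.items()}
        subs = {rid: v for rid, v in values.items()
                if rid not in set(self.ext.usage_reactions.values())}
        return GeneLevelSolution(sub_fluxes=subs, usage=usage, objective_value=objective)

    def expression_for(self, rid: str) -> dict:
        """Net-flux expression (column -> coefficient) for an original
        reaction id, valid on both plain and extended views."""
        if self.ext is None or rid in self.index and rid not in self.ext.parent_of:
            if rid in self.index:
                return {self.index[rid]: 1.0}
        if self.ext is not None and rid in self.ext.split_map:
            return {self.index[s.id]: (1.0 if s.direction == "fwd" else -1.0)
                    for s in self.ext.split_map[rid]}
        raise KeyError(f"unknown reaction id {rid!r}")


def _stack_eq(view: LinearView, extra_eq):
    """Equality system of the view plus extra rows given as (expr, rhs)."""
    n = len(view.ids)
    b = np.zeros(view.A.shape[0])
    blocks = [view.A]
    rhs = [b]
    for expr, value in extra_eq:
        row = np.zeros((1, n))
        for j, coef in expr.items():
            row[0, j] = coef
        blocks.append(sp.csr_matrix(row))
        rhs.append(np.array([value]))
    return sp.vstack(blocks).tocsr(), np.concatenate(rhs)


def _ub_rows(n, extra_ub):
    if not extra_ub:
        return None, None
    rows = []
    rhs = []
    for expr, value in extra_ub:
        row = np.zeros(n)
        for j, coef in expr.items():
            row[j] = coef
        rows.append(row)
        rhs.append(value)
    return sp.csr_matrix(np.vstack(rows)), np.array(rhs)


def _result(view: LinearView, res: LPResult, objective: float | None,
            diagnostics=False, metadata=None) -> SimulationResult:
    if not res.optimal:
        return SimulationResult(status=res.status, metadata=metadata or {})
    sol = view.solution_from(res.x, objective)
    diag = None
    if diagnostics:
        diag = {"shadow_prices": res.duals_eq, "reduced_costs": res.reduced_costs}
    return SimulationResult(status="optimal", solution=sol,
                            objective_value=objective,
                            diagnostics=diag, metadata=metadata or {})


def _maximize_growth(view: LinearView, extra_eq=(), extra_ub=()):
    c = -view.growth_vector()
    A_eq, b_eq = _stack_eq(view, extra_eq)
    A_ub, b_ub = _ub_rows(len(view.ids), list(extra_ub))
    res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=view.bounds,
                   A_ub=A_ub, b_ub=b_ub)
    return res


# ---------------------------------------------------------------------------
# FBA / pFBA
# ---------------------------------------------------------------------------


def fba(m, objective_sense: str = "max", tie_break: bool = False,
        diagnostics: bool = False) -> SimulationResult:
    """Flux balance analysis: optimize the objective flux subject to
    ``S.v = 0`` and bounds.  ``tie_break=True`` adds a second stage that
    minimizes the l1-norm of the flux vector at the fixed optimum, removing
    solver-dependent degeneracy."""
    view = LinearView(m)
    sign = -1.0 if objective_sense == "max" else 1.0
    c = sign * view.growth_vector()
    A_eq, b_eq = _stack_eq(view, [])
    res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=view.bounds)
    if not res.optimal:
        return SimulationResult(status=res.status)
    objective = sign * res.fun
    if tie_break:
        return _l1_stage(view, fixed_growth=objective, objective_value=objective)
    return _result(view, res, objective, diagnostics=diagnostics)


def _l1_stage(view: LinearView, fixed_growth: float | None, objective_value,
              weights: dict | None = None, extra_eq=(), extra_ub=(),
              metadata=None) -> SimulationResult:
    """Minimize a weighted l1-norm of fluxes, by default at fixed growth
    (``fixed_growth=None`` drops the growth row; pass the growth constraint
    via ``extra_ub`` instead).

    ``weights`` maps column index -> weight (default 1 for every column).
    Columns that can go negative receive an auxiliary |.| variable.
    """
    n = len(view.ids)
    eq = list(extra_eq)
    if fixed_growth is not None:
        eq.append((view.growth_expr, fixed_growth))
    A_eq, b_eq = _stack_eq(view, eq)
    A_ub, b_ub = _ub_rows(n, list(extra_ub))

    if weights is None:
        weights = {j: 1.0 for j in range(n)}
    aux_cols = [j for j, w in weights.items()
                if w != 0 and view.bounds[j][0] < 0]
    n_aux = len(aux_cols)
    c = np.zeros(n + n_aux)
    for j, w in weights.items():
        if j not in aux_cols:
            c[j] = w
    rows = []
    rhs = []
    for k, j in enumerate(aux_cols):
        c[n + k] = weights[j]
        r1 = np.zeros(n + n_aux)
        r1[j] = 1.0
        r1[n + k] = -1.0
        rows.append(r1)
        rhs.append(0.0)
        r2 = np.zeros(n + n_aux)
        r2[j] = -1.0
        r2[n + k] = -1.0
        rows.append(r2)
        rhs.append(0.0)
    A_eq2 = sp.hstack([A_eq, sp.csr_matrix((A_eq.shape[0], n_aux))]).tocsr()
    ub_blocks = []
    ub_rhs = []
    if A_ub is not None:
        ub_blocks.append(sp.hstack([A_ub, sp.csr_matrix((A_ub.shape[0], n_aux))]))
        ub_rhs.append(b_ub)
    if rows:
        ub_blocks.append(sp.csr_matrix(np.vstack(rows)))
        ub_rhs.append(np.array(rhs))
    A_ub2 = sp.vstack(ub_blocks).tocsr() if ub_blocks else None
    b_ub2 = np.concatenate(ub_rhs) if ub_blocks else None
    bounds = list(view.bounds) + [(0.0, None)] * n_aux
    res = solve_lp(c, A_eq=A_eq2, b_eq=b_eq, bounds=bounds, A_ub=A_ub2, b_ub=b_ub2)
    if not res.optimal:
        return SimulationResult(status=res.status, metadata=metadata or {})
    sol = view.solution_from(res.x[:n], objective_value)
    meta = dict(metadata or {})
    meta["norm_objective"] = res.fun
    return SimulationResult(status="optimal", solution=sol,
                            objective_value=objective_value, metadata=meta)


def pfba(m, level: str = "reaction") -> SimulationResult:
    """Parsimonious FBA.

    Stage 1 fixes growth at its FBA maximum; stage 2 minimizes total
    absolute flux through all reactions (``level="reaction"``) or total
    enzyme usage ``sum(u)`` (``level="gene"``, extended models only).
    Minimizing usage prices a k-subunit complex at k gene-units per flux
    unit, so flux is routed through enzymatically cheap paths.
    """
    view = LinearView(m)
    if level == "gene" and view.ext is None:
        raise ModelError("gene-level pFBA requires an extended model")
    res = _maximize_growth(view)
    if not res.optimal:
        return SimulationResult(status=res.status)
    vmax = -res.fun
    if level == "gene":
        weights = {j: 0.0 for j in range(len(view.ids))}
        for g, j in view.usage_columns().items():
            weights[j] = 1.0
    else:
        usage_cols = set(view.usage_columns().values())
        weights = {j: (0.0 if j in usage_cols else 1.0)
                   for j in range(len(view.ids))}
    out = _l1_stage(view, fixed_growth=vmax, objective_value=vmax,
                    weights=weights, metadata={"level": level})
    return out


# ---------------------------------------------------------------------------
# MOMA family
# ---------------------------------------------------------------------------


def _deletion_bounds(view: LinearView, deleted_genes, deleted_reactions):
    """Zero bounds implementing the deletions on this view (returns a new
    bounds list)."""
    bounds = list(view.bounds)

    def zero(j):
        bounds[j] = (0.0, 0.0)

    if deleted_genes:
        if view.ext is not None:
            for g in deleted_genes:
                if g not in view.ext.usage_reactions:
                    raise ModelError(f"unknown gene {g!r}")
                zero(view.index[view.ext.usage_reactions[g]])
        else:
            from .gpr import evaluate_gpr
            for rxn in view.model.reactions.values():
                if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, deleted_genes):
                    zero(view.index[rxn.id])
    if deleted_reactions:
        for rid in deleted_reactions:
            if view.ext is not None and rid in view.ext.split_map:
                for sub in view.ext.split_map[rid]:
                    zero(view.index[sub.id])
            elif rid in view.index:
                zero(view.index[rid])
            else:
                raise ModelError(f"unknown reaction {rid!r}")
    return bounds


def _reference_vector(view: LinearView, level: str, reference):
    """Reference flux/usage state for MOMA-type methods.  Defaults to the
    wild-type pFBA solution at the matching level."""
    if reference is None:
        reference = pfba(view.ext if view.ext is not None else view.model,
                         level=level)
    if isinstance(reference, SimulationResult):
        if not reference.optimal:
            raise ModelError("wild-type reference simulation is not optimal")
        reference = reference.solution
    if level == "gene":
        ref_map = reference.usage if isinstance(reference, GeneLevelSolution) else dict(reference)
        keys = list(view.usage_columns())
        cols = [view.usage_columns()[g] for g in keys]
    else:
        if isinstance(reference, GeneLevelSolution):
            from .transform import collapse_solution
            reference = collapse_solution(view.ext, reference)
        ref_map = reference.fluxes if isinstance(reference, FluxSolution) else dict(reference)
        if view.ext is None:
            keys = list(view.ids)
            cols = None  # identity over reaction columns
        else:
            keys = list(view.ext.split_map)
            cols = None
    return keys, ref_map


def _deviation_matrix(view: LinearView, level: str, keys):
    n = len(view.ids)
    rows = []
    for key in keys:
        row = np.zeros(n)
        if level == "gene":
            row[view.usage_columns()[key]] = 1.0
        else:
            for j, coef in view.expression_for(key).items():
                row[j] = coef
        rows.append(row)
    return sp.csr_matrix(np.vstack(rows))


def moma(m, deleted_genes=None, deleted_reactions=None, level: str = "gene",
         norm: str = "quadratic", reference=None) -> SimulationResult:
    """Minimization of metabolic adjustment after deletions.

    Minimizes the squared (``norm="quadratic"``) or absolute
    (``norm="linear"``) deviation from a wild-type reference over usage
    fluxes (``level="gene"``) or net reaction fluxes (``level="reaction"``),
    with the deleted genes' usages (or deleted reactions) forced to zero.
    The reference defaults to pFBA at the matching level, as the wild-type
    enzyme-usage vector is itself defined by parsimonious simulation.
    An infeasible deletion is reported as status ``infeasible`` (a lethality
    signal), not as an error.
    """
    view = LinearView(m)
    if level == "gene" and view.ext is None:
        raise ModelError("gene-level MOMA requires an extended model")
    if norm == "quadratic" and not qp_capable():
        raise SolverCapabilityError("quadratic MOMA requires a QP backend")
    keys, ref_map = _reference_vector(view, level, reference)
    P = _deviation_matrix(view, level, keys)
    r = np.array([ref_map.get(k, 0.0) for k in keys])
    bounds = _deletion_bounds(view, deleted_genes or (), deleted_reactions or ())
    A_eq, b_eq = _stack_eq(view, [])
    meta = {"level": level, "norm": norm,
            "deleted_genes": sorted(deleted_genes or ()),
            "deleted_reactions": sorted(deleted_reactions or ())}

    if norm == "quadratic":
        res = solve_qp(P, r, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        if not res.optimal:
            return SimulationResult(status=res.status, metadata=meta)
        x = res.x
        growth = float(view.growth_vector() @ x)
        sol = view.solution_from(x, growth)
        meta["deviation"] = res.fun
        return SimulationResult(status="optimal", solution=sol,
                                objective_value=growth, metadata=meta)

    # linear norm: min sum t, t >= +-(Px - r)
    n = len(view.ids)
    k = P.shape[0]
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq2 = sp.hstack([A_eq, sp.csr_matrix((A_eq.shape[0], k))]).tocsr()
    I = sp.identity(k)
    A_ub = sp.vstack([sp.hstack([P, -I]), sp.hstack([-P, -I])]).tocsr()
    b_ub = np.concatenate([r, -r])
    bounds2 = bounds + [(0.0, None)] * k
    res = solve_lp(c, A_eq=A_eq2, b_eq=b_eq, bounds=bounds2, A_ub=A_ub, b_ub=b_ub)
    if not res.optimal:
        return SimulationResult(status=res.status, metadata=meta)
    x = res.x[:n]
    growth = float(view.growth_vector() @ x)
    sol = view.solution_from(x, growth)
    meta["deviation"] = res.fun
    return SimulationResult(status="optimal", solution=sol,
                            objective_value=growth, metadata=meta)


# ---------------------------------------------------------------------------
# expression modulation
# ---------------------------------------------------------------------------


def simulate_modulation(ext: ExtendedModel, gene: str, lam: float,
                        reference=None, tie_break: bool = False) -> SimulationResult:
    """Over/under-expression of one gene at relative level ``lam``.

    The wild-type usage ``u_wt`` (gene-pFBA by default) anchors the
    constraint: ``u >= lam*u_wt`` for over-expression (lam > 1) and
    ``u <= lam*u_wt`` for under-expression (lam < 1); growth is then
    maximized.  ``lam == 1`` returns the unconstrained optimum.  ``lam <= 0``
    is rejected: use a knockout for full deletion.
    """
    if lam <= 0:
        raise ModelError("lambda must be > 0; use a gene knockout for 0")
    view = LinearView(ext)
    if gene not in ext.usage_reactions:
        raise ModelError(f"unknown gene {gene!r}")
    if reference is None:
        reference = pfba(ext, level="gene")
    uwt = (reference.solution.usage[gene]
           if isinstance(reference, SimulationResult) else reference[gene])
    j = view.index[ext.usage_reactions[gene]]
    bounds = list(view.bounds)
    if lam > 1:
        bounds[j] = (lam * uwt, bounds[j][1])
    elif lam < 1:
        bounds[j] = (bounds[j][0], lam * uwt)
    A_eq, b_eq = _stack_eq(view, [])
    res = solve_lp(-view.growth_vector(), A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    if not res.optimal:
        return SimulationResult(status=res.status,
                                metadata={"gene": gene, "lambda": lam, "u_wt": uwt})
    growth = -res.fun
    meta = {"gene": gene, "lambda": lam, "u_wt": uwt}
    if tie_break:
        sub = LinearView(ext)
        sub.bounds = bounds
        return _l1_stage(sub, fixed_growth=growth, objective_value=growth,
                         metadata=meta)
    return _result(view, res, growth, metadata=meta)


# ---------------------------------------------------------------------------
# FVA and essentiality
# ---------------------------------------------------------------------------


def fva(m, variables=None, growth_fraction: float | None = None) -> dict:
    """Flux variability analysis.

    Returns ``{variable: (min, max)}`` subject to
    ``growth >= growth_fraction * FBA max`` when a fraction is given.
    ``variables`` may name reactions, sub-reactions, or (on extended models)
    genes, whose usage reactions are then analyzed; default: every column.
    """
    view = LinearView(m)
    extra_ub = []
    if growth_fraction is not None:
        res = _maximize_growth(view)
        if not res.optimal:
            raise ModelError(f"FVA baseline is {res.status}")
        vmax = -res.fun
        extra_ub.append(({j: -c for j, c in view.growth_expr.items()},
                         -growth_fraction * vmax))
    usage_cols = view.usage_columns()
    if variables is None:
        targets = list(view.ids)
    else:
        targets = list(variables)
    A_eq, b_eq = _stack_eq(view, [])
    A_ub, b_ub = _ub_rows(len(view.ids), extra_ub)
    out = {}
    for t in targets:
        if t in view.index:
            expr = {view.index[t]: 1.0}
        elif t in usage_cols:
            expr = {usage_cols[t]: 1.0}
        elif view.ext is not None and t in view.ext.split_map:
            expr = view.expression_for(t)
        else:
            raise ModelError(f"unknown FVA variable {t!r}")
        c = np.zeros(len(view.ids))
        for j, coef in expr.items():
            c[j] = coef
        lo = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=view.bounds, A_ub=A_ub, b_ub=b_ub)
        hi = solve_lp(-c, A_eq=A_eq, b_eq=b_eq, bounds=view.bounds, A_ub=A_ub, b_ub=b_ub)
        if not (lo.optimal and hi.optimal):
            raise ModelError(f"FVA subproblem for {t!r} is not optimal")
        out[t] = (lo.fun, -hi.fun)
    return out


def gene_essentiality(ext: ExtendedModel, growth_fraction: float = 0.1,
                      tol: float = ESSENTIALITY_TOL):
    """Gene essentiality by FVA of the enzyme-usage variables.

    A gene whose *minimal* usage at ``growth >= growth_fraction * max`` is
    above tolerance is essential (its enzyme must carry flux in every state
    that sustains the required growth); a gene whose *maximal* usage is at
    tolerance is blocked (its enzyme can never be used).  Returns a pandas
    DataFrame indexed by gene with columns min_usage, max_usage, essential,
    blocked.  An infeasible baseline raises instead of reporting every gene
    essential.
    """
    import pandas as pd

    ranges = fva(ext, variables=ext.genes, growth_fraction=growth_fraction)
    rows = {}
    for g, (lo, hi) in ranges.items():
        rows[g] = {
            "min_usage": lo,
            "max_usage": hi,
            "essential": lo > tol,
            "blocked": hi <= tol,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
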