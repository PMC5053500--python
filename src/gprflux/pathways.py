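"""Elementary flux modes and brute-force constrained minimal cut sets.

EFMs are computed with a double-description style algorithm on the
direction-split (all-nonnegative) network.  On an extended model the enzyme
usage reactions become part of each mode's support, so the gene content of
every minimal pathway can be read off directly.

Cut sets are enumerated exhaustively (subset enumeration with superset
pruning) at desk scale: a deletion set is a constrained minimal cut set when
it makes the *undesired* flux region (growth without sufficient product
yield) infeasible while keeping the *desired* region (growth-coupled
production) feasible.  On an extended model with usage reactions as
deletion targets, the enumeration yields gene-based designs whose side
effects are implicitly accounted for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .gpr import CapacityError, evaluate_gpr, minimal_knockout_sets
from .model import MetabolicModel, ModelError
from .simulate import LinearView, _stack_eq, _ub_rows
from .solver import solve_lp
from .transform import ExtendedModel, split_directions

__all__ = [
    "ElementaryMode",
    "CutSetDesign",
    "ProductionScenario",
    "compute_efms",
    "frequency_analysis",
    "enumerate_cut_sets",
    "expand_to_gene_designs",
    "validate_design",
]

EFM_GUARD = 40
EFM_TOL = 1e-9
CUT_TOL = 1e-6


# ---------------------------------------------------------------------------
# elementary flux modes
# ---------------------------------------------------------------------------


@dataclass
class ElementaryMode:
    """A support-minimal steady-state flux pattern, normalized so its
    largest coefficient is 1."""

    flux_pattern: dict  # sub-reaction id -> coefficient (support only)
    support: frozenset
    gene_support: frozenset = frozenset()

    def __contains__(self, rid):
        return rid in self.support


def _minimal_rays(rays: list) -> list:
    """Keep rays whose support is not a proper superset of another's."""
    supports = [frozenset(np.flatnonzero(np.abs(r) > EFM_TOL)) for r in rays]
    keep = []
    for i, si in enumerate(supports):
        dominated = any(
            sj < si or (sj == si and j < i)
            for j, sj in enumerate(supports) if j != i
        )
        if not dominated:
            keep.append(rays[i])
    return keep


def _enumerate_rays(S: np.ndarray) -> list:
    """Extreme rays of {v >= 0 : S v = 0} by iterative row processing with
    the combinatorial (support-minimality) adjacency test."""
    m, n = S.shape
    rays = [np.eye(n)[j] for j in range(n)]
    for i in range(m):
        h = S[i]
        vals = [float(h @ r) for r in rays]
        zero = [r for r, v in zip(rays, vals) if abs(v) <= EFM_TOL]
        pos = [(r, v) for r, v in zip(rays, vals) if v > EFM_TOL]
        neg = [(r, v) for r, v in zip(rays, vals) if v < -EFM_TOL]
        new = list(zero)
        for (rp, vp), (rn, vn) in itertools.product(pos, neg):
            w = vp * rn - vn * rp  # h.w = 0, nonnegative combination
            mx = w.max()
            if mx > EFM_TOL:
                new.append(w / mx)
        rays = _minimal_rays(new)
    return rays


def compute_efms(m, guard: int = EFM_GUARD) -> list:
    """Enumerate all elementary flux modes of a desk-scale network.

    Reversible reactions are direction-split first (spurious two-cycles
    formed by a forward/backward pair of the same parent are discarded).
    On an extended model, each mode's ``gene_support`` lists the genes whose
    usage reactions are in its support.  Models larger than ``guard``
    sub-reactions raise :class:`CapacityError`; use dedicated large-scale
    tools beyond that.
    """
    if isinstance(m, ExtendedModel):
        ext = m
        model = m.base
    else:
        if any(r.reversible for r in m.reactions.values()):
            ext = split_directions(m)
            model = ext.base
        else:
            ext = None
            model = m
    if len(model.reactions) > guard:
        raise CapacityError(
            f"{len(model.reactions)} sub-reactions exceed the EFM guard of "
            f"{guard}; use a dedicated large-scale EFM tool")
    view = LinearView(ext if ext is not None else model)
    S = view.A.toarray()
    ids = view.ids
    rays = _enumerate_rays(S)

    usage_of = {}
    if isinstance(m, ExtendedModel):
        usage_of = {rid: g for g, rid in m.usage_reactions.items()}

    def parent_dir(rid):
        if ext is None:
            return rid, "fwd"
        sub = next((s for s in ext.split_map.get(ext.parent_of.get(rid, ""), [])
                    if s.id == rid), None)
        return (sub.parent, sub.direction) if sub else (rid, "fwd")

    modes = []
    seen = set()
    for ray in rays:
        support_idx = np.flatnonzero(np.abs(ray) > EFM_TOL)
        support = frozenset(ids[j] for j in support_idx)
        if not support:
            continue
        if len(support) == 2:  # futile fwd/bwd pair of one parent reaction
            (p1, d1), (p2, d2) = (parent_dir(r) for r in support)
            if p1 == p2 and d1 != d2:
                continue
        if support in seen:
            continue
        seen.add(support)
        coefs = ray / ray[support_idx].max()
        pattern = {ids[j]: float(coefs[j]) for j in support_idx}
        genes = frozenset(usage_of[r] for r in support if r in usage_of)
        modes.append(ElementaryMode(flux_pattern=pattern, support=support,
                                    gene_support=genes))
    modes.sort(key=lambda e: sorted(e.support))
    return modes


def frequency_analysis(modes: list, m):
    """Participation fractions per gene and per original reaction.

    A gene participates in a mode when it is in the mode's gene support; a
    reaction participates when any of its sub-reactions is in the support.
    Returns ``(gene_freq, reaction_freq)`` as pandas Series.
    """
    import pandas as pd

    if not modes:
        raise ModelError("empty mode set")
    total = len(modes)
    if isinstance(m, ExtendedModel):
        genes = m.genes
        reactions = list(m.split_map)
        sub_ids = {rid: {s.id for s in subs} for rid, subs in m.split_map.items()}
    else:
        genes = m.genes
        reactions = list(m.reactions)
        sub_ids = {rid: {rid, f"{rid}__fwd", f"{rid}__bwd"} for rid in reactions}
    gene_freq = pd.Series(
        {g: sum(1 for e in modes if g in e.gene_support) / total for g in genes},
        dtype=float).sort_index()
    rxn_freq = pd.Series(
        {rid: sum(1 for e in modes if e.support & sub_ids[rid]) / total
         for rid in reactions}, dtype=float).sort_index()
    return gene_freq, rxn_freq


# ---------------------------------------------------------------------------
# constrained minimal cut sets (brute force at desk scale)
# ---------------------------------------------------------------------------


@dataclass
class ProductionScenario:
    """A growth-coupling design goal.

    ``substrate``/``product`` are exchange reaction ids; uptake is measured
    positively in the uptake direction.  The desired region requires growth
    at least ``mu_min`` with product yield at least ``y_min`` (mol product
    per mol substrate); the undesired region is any state with growth at
    least ``mu_min`` but a lower yield.  ``extra_bounds`` (reaction id ->
    (lb, ub)) model the cultivation condition, e.g. closing oxygen uptake
    for an anaerobic scenario.
    """

    substrate: str
    product: str
    mu_min: float = 0.001
    y_min: float = 1.4
    extra_bounds: dict = field(default_factory=dict)


@dataclass
class CutSetDesign:
    """A deletion set (reaction- or gene-identified) with its verdict."""

    targets: frozenset
    kind: str  # "reaction" | "gene"
    effective_reaction_deletions: frozenset = frozenset()
    feasible: bool | None = None

    @property
    def size(self) -> int:
        return len(self.targets)


def _uptake_expression(view: LinearView, rid: str) -> dict:
    """Expression whose value is the (positive) uptake rate through an
    exchange reaction."""
    model = view.ext.source if view.ext is not None else view.model
    rxn = model.reactions[rid]
    coef = next(iter(rxn.stoichiometry.values()))
    sign = 1.0 if coef > 0 else -1.0  # forward flux imports iff coef > 0
    return {j: sign * c for j, c in view.expression_for(rid).items()}


def _scenario_bounds(view: LinearView, scenario: ProductionScenario,
                     deletions) -> list:
    bounds = list(view.bounds)
    for rid, (lb, ub) in scenario.extra_bounds.items():
        if view.ext is not None and rid in view.ext.split_map:
            for sub in view.ext.split_map[rid]:
                if sub.direction == "fwd":
                    bounds[view.index[sub.id]] = (max(lb, 0.0), max(ub, 0.0))
                else:
                    bounds[view.index[sub.id]] = (max(-ub, 0.0), max(-lb, 0.0))
        elif rid in view.index:
            bounds[view.index[rid]] = (lb, ub)
        else:
            raise ModelError(f"unknown reaction {rid!r} in scenario bounds")
    # deletions: reaction ids, sub-reaction ids, or gene ids on extended views
    for target in deletions:
        if view.ext is not None and target in view.ext.usage_reactions:
            bounds[view.index[view.ext.usage_reactions[target]]] = (0.0, 0.0)
        elif view.ext is not None and target in view.ext.split_map:
            for sub in view.ext.split_map[target]:
                bounds[view.index[sub.id]] = (0.0, 0.0)
        elif target in view.index:
            bounds[view.index[target]] = (0.0, 0.0)
        else:
            raise ModelError(f"unknown deletion target {target!r}")
    return bounds


def _region_tests(view: LinearView, scenario: ProductionScenario, deletions):
    """(undesired_cut, desired_feasible) LP verdicts after ``deletions``."""
    bounds = _scenario_bounds(view, scenario, deletions)
    A_eq, b_eq = _stack_eq(view, [])
    n = len(view.ids)
    growth = view.growth_expr
    product = view.expression_for(scenario.product)
    uptake = _uptake_expression(view, scenario.substrate)

    yield_expr = dict(product)
    for j, c in uptake.items():
        yield_expr[j] = yield_expr.get(j, 0.0) - scenario.y_min * c

    # undesired region cut? minimize yield margin at growth >= mu_min
    growth_row = ({j: -c for j, c in growth.items()}, -scenario.mu_min)
    A_ub, b_ub = _ub_rows(n, [growth_row])
    c_vec = np.zeros(n)
    for j, c in yield_expr.items():
        c_vec[j] = c
    res = solve_lp(c_vec, A_eq=A_eq, b_eq=b_eq, bounds=bounds, A_ub=A_ub, b_ub=b_ub)
    if res.status == "infeasible":
        undesired_cut = True  # no growth state at all: trivially cut
    elif res.optimal:
        undesired_cut = res.fun >= -CUT_TOL
    else:
        undesired_cut = False

    # desired region feasible? growth >= mu_min and yield margin >= 0
    rows = [growth_row, ({j: -c for j, c in yield_expr.items()}, 0.0)]
    A_ub2, b_ub2 = _ub_rows(n, rows)
    res2 = solve_lp(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                    A_ub=A_ub2, b_ub=b_ub2)
    return undesired_cut, res2.optimal


def enumerate_cut_sets(m, scenario: ProductionScenario, targetable,
                       max_size: int = 3, guard: int = 1_000_000) -> list:
    """All inclusion-minimal deletion sets (up to ``max_size``) that couple
    production to growth, by exhaustive subset enumeration.

    On an extended model with gene ids (or usage reactions) as targets the
    result is a list of gene-based designs; on a plain model, reaction-based
    designs.  Every returned design has passed both LP region tests, so its
    ``feasible`` verdict is True by construction.
    """
    view = LinearView(m)
    targetable = sorted(targetable)
    total = sum(1 for k in range(1, max_size + 1)
                for _ in itertools.combinations(range(len(targetable)), k))
    if total > guard:
        raise CapacityError(f"{total} candidate subsets exceed the guard {guard}")
    kind = ("gene" if isinstance(m, ExtendedModel)
            and all(t in m.usage_reactions or t in set(m.usage_reactions.values())
                    for t in targetable) else "reaction")
    found: list = []
    found_sets: list = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(targetable, size):
            cs = frozenset(combo)
            if any(prev <= cs for prev in found_sets):
                continue  # superset of a minimal cut set
            cut, desired = _region_tests(view, scenario, combo)
            if cut and desired:
                found_sets.append(cs)
                effective = _effective_deletions_of(m, combo)
                found.append(CutSetDesign(targets=cs, kind=kind,
                                          effective_reaction_deletions=effective,
                                          feasible=True))
    return sorted(found, key=lambda d: (d.size, sorted(d.targets)))


def _effective_deletions_of(m, targets) -> frozenset:
    if isinstance(m, ExtendedModel):
        genes = {t for t in targets if t in m.usage_reactions}
        rxns = {t for t in targets if t in m.split_map}
        model = m.source
        eff = set(rxns)
        if genes:
            for rxn in model.reactions.values():
                if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, genes):
                    eff.add(rxn.id)
        return frozenset(eff)
    return frozenset(targets)


def expand_to_gene_designs(design: CutSetDesign, model: MetabolicModel,
                           cap: int = 100_000) -> list:
    """Translate a reaction-based cut set into all candidate gene-based
    designs (Cartesian combination of the per-reaction minimal knockout
    sets, minimized across reactions).

    Shared subunits make some combinations collapse or become non-minimal,
    so the result can be smaller than the naive product.  A target reaction
    without GPR cannot be deleted genetically and raises an error.
    """
    per_target = []
    for rid in sorted(design.targets):
        rxn = model.reactions.get(rid)
        if rxn is None:
            raise ModelError(f"unknown reaction {rid!r}")
        if rxn.gpr is None:
            raise ModelError(f"reaction {rid!r} has no GPR; not deletable "
                             "by genetic means")
        per_target.append(minimal_knockout_sets(rxn.gpr))
    combos: set = set()
    n_total = 1
    for ks in per_target:
        n_total *= len(ks)
    if n_total > cap:
        raise CapacityError(f"{n_total} gene combinations exceed the cap {cap}")
    for combo in itertools.product(*per_target):
        genes = frozenset().union(*combo)
        combos.add(genes)
    minimal = [g for g in combos if not any(o < g for o in combos)]
    return [CutSetDesign(targets=g, kind="gene")
            for g in sorted(minimal, key=lambda s: (len(s), sorted(s)))]


def validate_design(design: CutSetDesign, model: MetabolicModel,
                    scenario: ProductionScenario) -> CutSetDesign:
    """Audit a gene-based design against the original model.

    Computes the reactions *effectively* disabled by the gene deletions
    (every reaction whose GPR evaluates false, capturing promiscuity side
    effects), applies those reaction deletions, and re-runs both LP region
    tests.  Infeasibility is a verdict, not an error.
    """
    deleted = set(design.targets)
    effective = {rxn.id for rxn in model.reactions.values()
                 if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, deleted)}
    view = LinearView(model)
    cut, desired = _region_tests(view, scenario, sorted(effective))
    return CutSetDesign(targets=design.targets, kind="gene",
                        effective_reaction_deletions=frozenset(effective),
                        feasible=bool(cut and desired))
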