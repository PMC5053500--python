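"""Transcriptomics-constrained simulation: GIMME and E-Flux.

Both methods exist at two levels.  The conventional reaction-level variants
map gene expression onto reactions through the GPR rule (AND -> minimum over
subunits, OR -> sum over isozymes) and then penalize or cap reaction fluxes.
The gene-level variants avoid that lossy mapping altogether: expression
values address the enzyme-usage variables ``u`` of the extended model
directly, which is the reason the extended representation exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, ModelError
from .simulate import (LinearView, SimulationResult, _l1_stage,
                       _maximize_growth, _stack_eq)
from .solver import solve_lp

logger = logging.getLogger(__name__)

__all__ = ["ExpressionProfile", "read_expression", "gimme", "eflux"]


@dataclass
class ExpressionProfile:
    """Gene expression levels (arbitrary nonnegative units) for one condition."""

    values: dict
    condition: str = ""

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ModelError("expression values must be nonnegative")
        if self.values and max(self.values.values()) <= 0:
            raise ModelError("expression profile needs at least one positive value")

    def matched(self, genes) -> dict:
        """Subset of values whose genes exist in the model; unmatched genes
        are reported via logging and excluded from constraints."""
        genes = set(genes)
        unmatched = sorted(set(self.values) - genes)
        if unmatched:
            logger.warning("expression profile %s: %d genes not in model (%s...)",
                           self.condition, len(unmatched), ", ".join(unmatched[:5]))
        return {g: v for g, v in self.values.items() if g in genes}


def read_expression(path, condition: str = "") -> ExpressionProfile:
    """Read a tab-separated gene/value table (optional single header line)."""
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ModelError(f"line {lineno}: expected two tab-separated columns")
            gene, val = parts[0].strip(), parts[1].strip()
            try:
                v = float(val)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ModelError(f"line {lineno}: non-numeric value {val!r}") from None
            if v < 0:
                raise ModelError(f"line {lineno}: negative expression for {gene!r}")
            if gene in values:
                raise ModelError(f"line {lineno}: duplicated gene id {gene!r}")
            values[gene] = v
    return ExpressionProfile(values=values, condition=condition or str(path))


def _gpr_expression_value(node, values):
    """Map expression onto a GPR expression tree: AND -> min, OR -> sum.
    Unmeasured genes are ignored; returns None if nothing is measured."""
    from .gpr import _And, _Or, _Var

    if isinstance(node, _Var):
        return values.get(node.gene)
    parts = [_gpr_expression_value(c, values) for c in node.children]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    return min(parts) if isinstance(node, _And) else sum(parts)


def reaction_expression(model: MetabolicModel, values: dict) -> dict:
    """Reaction-level expression scores via the AND=min / OR=sum convention."""
    out = {}
    for rxn in model.reactions.values():
        if rxn.gpr is None:
            continue
        score = _gpr_expression_value(rxn.gpr._ast, values)
        if score is not None:
            out[rxn.id] = score
    return out


def gimme(m, profile: ExpressionProfile, level: str = "gene",
          growth_fraction: float = 0.85, cutoff_percentile: float = 25,
          equality: bool = True) -> SimulationResult:
    """GIMME: minimize flux through lowly-expressed activity at near-optimal
    growth.

    The cutoff is the ``cutoff_percentile``-th percentile of the measured
    expression values (linear interpolation between order statistics).  A
    gene (or mapped reaction) below the cutoff receives the penalty
    ``c = cutoff - e``; the objective ``min sum(c_i * u_i)`` (gene level) or
    ``min sum(c_r * |v_r|)`` (reaction level) is solved with growth fixed at
    ``growth_fraction`` of the FBA maximum (equality by default; set
    ``equality=False`` for the conventional >= form).
    """
    view = LinearView(m)
    if level == "gene" and view.ext is None:
        raise ModelError("gene-level GIMME requires an extended model")
    genes = view.ext.genes if view.ext is not None else view.model.genes
    values = profile.matched(genes)
    if not values or max(values.values()) <= 0:
        raise ModelError("degenerate (all-zero or empty) expression profile")
    cutoff = float(np.percentile(list(values.values()), cutoff_percentile))

    res = _maximize_growth(view)
    if not res.optimal:
        return SimulationResult(status=res.status)
    target = growth_fraction * (-res.fun)

    if level == "gene":
        penalties = {}
        for g, col in view.usage_columns().items():
            e = values.get(g)
            if e is not None and e < cutoff:
                penalties[col] = cutoff - e
    else:
        scores = reaction_expression(
            view.ext.source if view.ext is not None else view.model, values)
        penalties = {}
        for rid, e in scores.items():
            if e < cutoff:
                if view.ext is None:
                    penalties[view.index[rid]] = cutoff - e
                else:
                    for sub in view.ext.split_map[rid]:
                        penalties[view.index[sub.id]] = cutoff - e

    weights = {j: penalties.get(j, 0.0) for j in range(len(view.ids))}
    meta = {"cutoff": cutoff, "growth_target": target, "level": level,
            "percentile_method": "linear interpolation"}
    if equality:
        out = _l1_stage(view, fixed_growth=target, objective_value=target,
                        weights=weights, metadata=meta)
    else:
        extra_ub = [({j: -c for j, c in view.growth_expr.items()}, -target)]
        out = _l1_stage(view, fixed_growth=None, objective_value=None,
                        weights=weights, extra_ub=extra_ub, metadata=meta)
    if out.optimal:
        out.objective_value = out.metadata.pop("norm_objective", None)
    return out


def eflux(m, profile: ExpressionProfile, measured_uptake: float,
          substrate: str, level: str = "gene") -> SimulationResult:
    """E-Flux: expression-normalized flux caps, then uptake rescaling.

    Step 1 maximizes growth with caps ``e_i / max(e)`` on the usage
    variables (gene level) or on the mapped reaction fluxes (reaction
    level); unmeasured genes/reactions are not capped.  Step 2 multiplies
    the whole flux vector by ``measured_uptake / |v_substrate|`` so the
    substrate uptake matches the measurement exactly (uniform scaling
    preserves all steady-state balances).  A zero step-1 uptake makes the
    rescaling undefined and raises an error.
    """
    if measured_uptake <= 0:
        raise ModelError("measured uptake must be positive")
    view = LinearView(m)
    if level == "gene" and view.ext is None:
        raise ModelError("gene-level E-Flux requires an extended model")
    genes = view.ext.genes if view.ext is not None else view.model.genes
    values = profile.matched(genes)
    if not values or max(values.values()) <= 0:
        raise ModelError("degenerate expression profile")
    emax = max(values.values())

    bounds = list(view.bounds)
    if level == "gene":
        for g, col in view.usage_columns().items():
            if g in values:
                lb, ub = bounds[col]
                bounds[col] = (lb, min(ub, values[g] / emax))
    else:
        scores = reaction_expression(
            view.ext.source if view.ext is not None else view.model, values)
        for rid, e in scores.items():
            cap = e / emax
            if view.ext is None:
                lb, ub = bounds[view.index[rid]]
                bounds[view.index[rid]] = (max(lb, -cap) if lb < 0 else lb,
                                           min(ub, cap))
            else:
                for sub in view.ext.split_map[rid]:
                    lb, ub = bounds[view.index[sub.id]]
                    bounds[view.index[sub.id]] = (lb, min(ub, cap))

    # the substrate exchange must be free to fall below its medium bound
    source = view.ext.source if view.ext is not None else view.model
    if substrate not in source.reactions:
        raise ModelError(f"unknown substrate exchange {substrate!r}")

    A_eq, b_eq = _stack_eq(view, [])
    res = solve_lp(-view.growth_vector(), A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    if not res.optimal:
        return SimulationResult(status=res.status)
    x = res.x
    sub_expr = view.expression_for(substrate)
    v_sub = abs(sum(coef * x[j] for j, coef in sub_expr.items()))
    if v_sub <= 1e-12:
        raise ModelError("step-1 substrate uptake is zero; rescaling undefined")
    scale = measured_uptake / v_sub
    growth = -res.fun * scale
    sol = view.solution_from(x * scale, growth)
    return SimulationResult(status="optimal", solution=sol, objective_value=growth,
                            metadata={"scale": scale, "substrate": substrate,
                                      "level": level, "step1_uptake": v_sub})
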