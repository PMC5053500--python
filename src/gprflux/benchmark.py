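"""Prediction-error benchmarking of simulation methods against measured fluxes.

The error metric is the l1 (Manhattan) norm of the difference between
simulated and experimental fluxes over the experimentally measured
reactions, normalized by the l1-norm of the experimental fluxes:

    error = ||v_sim - v_exp||_1 / ||v_exp||_1

The harness runs a list of reaction- and gene-level methods on a set of
conditions (each a substrate uptake measurement plus optional gene
deletions and an expression profile) and reports the per-condition,
per-method error, mirroring how flux-prediction methods are compared
against 13C fluxomics datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import MetabolicModel, ModelError
from .omics import ExpressionProfile, eflux, gimme
from .simulate import SimulationResult, fba, moma, pfba
from .transform import collapse_solution, transform_model
from .gpr import evaluate_gpr

logger = logging.getLogger(__name__)

__all__ = ["Condition", "BenchmarkDataset", "normalized_error", "run_benchmark"]


@dataclass
class Condition:
    name: str
    substrate_exchange: str
    uptake_value: float
    deleted_genes: tuple = ()


@dataclass
class BenchmarkDataset:
    """Conditions plus per-condition expression profiles and measured fluxes."""

    conditions: list
    measured_fluxes: dict  # condition name -> {reaction id: flux}
    expression: dict = field(default_factory=dict)  # condition name -> profile


def normalized_error(v_sim, v_exp) -> float:
    """l1 prediction error over the measured reactions, scale-invariant in
    the common flux unit."""
    v_exp = dict(v_exp)
    if not v_exp:
        raise ModelError("no experimental fluxes given")
    v_sim = dict(v_sim)
    missing = set(v_exp) - set(v_sim)
    if missing:
        raise ModelError(f"simulated fluxes missing reactions {sorted(missing)[:5]}")
    denom = sum(abs(v) for v in v_exp.values())
    if denom <= 0:
        raise ModelError("experimental flux vector has zero l1-norm")
    num = sum(abs(v_sim[r] - v_exp[r]) for r in v_exp)
    return num / denom


GENE_LEVEL_METHODS = {"gene-pfba", "gene-moma", "gene-lmoma", "gene-gimme",
                      "gene-eflux"}
KNOWN_METHODS = GENE_LEVEL_METHODS | {"fba", "pfba", "moma", "lmoma", "gimme",
                                      "eflux"}


def _fix_uptake(model: MetabolicModel, rid: str, value: float) -> None:
    rxn = model.reactions[rid]
    coef = next(iter(rxn.stoichiometry.values()))
    if coef > 0:  # forward flux imports the metabolite
        rxn.lower_bound, rxn.upper_bound = value, value
    else:
        rxn.lower_bound, rxn.upper_bound = -value, -value


def _condition_models(model: MetabolicModel, cond: Condition):
    """(reaction-level model, extended model) with the uptake constraint and
    deletions applied the way each method family can express them: GPR-
    evaluated reaction deletions at reaction level, usage knockouts at gene
    level."""
    m = model.copy()
    if cond.substrate_exchange not in m.reactions:
        raise ModelError(f"unknown substrate exchange {cond.substrate_exchange!r}")
    _fix_uptake(m, cond.substrate_exchange, cond.uptake_value)
    ext = transform_model(m)
    for g in cond.deleted_genes:
        rid = ext.usage_reactions.get(g)
        if rid is None:
            raise ModelError(f"unknown gene {g!r}")
        ext.base.reactions[rid].lower_bound = 0.0
        ext.base.reactions[rid].upper_bound = 0.0
    m_rxn = m.copy()
    if cond.deleted_genes:
        for rxn in m_rxn.reactions.values():
            if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, cond.deleted_genes):
                rxn.lower_bound = rxn.upper_bound = 0.0
    return m_rxn, ext


def _run_method(method: str, m_rxn, ext, cond: Condition,
                profile: ExpressionProfile | None,
                wt_model: MetabolicModel) -> SimulationResult:
    if method == "fba":
        return fba(m_rxn, tie_break=True)
    if method == "pfba":
        return pfba(m_rxn)
    if method == "gene-pfba":
        return pfba(ext, level="gene")
    if method in ("moma", "lmoma"):
        # wild-type reference from the undeleted model, then reaction deletions
        ref = pfba(wt_model)
        return moma(m_rxn, level="reaction",
                    norm="quadratic" if method == "moma" else "linear",
                    reference=ref)
    if method in ("gene-moma", "gene-lmoma"):
        wt_ext = transform_model(wt_model)
        ref = pfba(wt_ext, level="gene")
        return moma(ext, deleted_genes=cond.deleted_genes, level="gene",
                    norm="quadratic" if method == "gene-moma" else "linear",
                    reference=ref)
    if method in ("gimme", "gene-gimme"):
        if profile is None:
            raise ModelError(f"{method} needs an expression profile")
        return gimme(ext if method.startswith("gene") else m_rxn, profile,
                     level="gene" if method.startswith("gene") else "reaction")
    if method in ("eflux", "gene-eflux"):
        if profile is None:
            raise ModelError(f"{method} needs an expression profile")
        return eflux(ext if method.startswith("gene") else m_rxn, profile,
                     measured_uptake=cond.uptake_value,
                     substrate=cond.substrate_exchange,
                     level="gene" if method.startswith("gene") else "reaction")
    raise ModelError(f"unknown method {method!r}")


def run_benchmark(model: MetabolicModel, dataset: BenchmarkDataset,
                  methods=("pfba", "gene-pfba")):
    """Per-condition, per-method normalized prediction errors as a pandas
    DataFrame (rows: conditions, columns: methods; NaN where a method is
    infeasible or a condition is skipped)."""
    import numpy as np
    import pandas as pd

    for method in methods:
        if method not in KNOWN_METHODS:
            raise ModelError(f"unknown method {method!r}")
    rows = {}
    for cond in dataset.conditions:
        measured = dataset.measured_fluxes.get(cond.name)
        if not measured:
            logger.warning("condition %s: no measured fluxes; skipped", cond.name)
            continue
        unresolvable = [r for r in measured if r not in model.reactions]
        if unresolvable:
            logger.warning("condition %s: unresolvable reaction ids %s; skipped",
                           cond.name, unresolvable)
            continue
        try:
            m_rxn, ext = _condition_models(model, cond)
        except ModelError as exc:
            logger.warning("condition %s: %s; skipped", cond.name, exc)
            continue
        wt_model = model.copy()
        _fix_uptake(wt_model, cond.substrate_exchange, cond.uptake_value)
        profile = dataset.expression.get(cond.name)
        row = {}
        for method in methods:
            res = _run_method(method, m_rxn, ext, cond, profile, wt_model)
            if not res.optimal:
                row[method] = np.nan
                continue
            if isinstance(res.solution, dict) or hasattr(res.solution, "sub_fluxes"):
                fluxes = collapse_solution(ext, res.solution).fluxes
            else:
                fluxes = res.solution.fluxes
            row[method] = normalized_error(
                {r: fluxes[r] for r in measured}, measured)
        rows[cond.name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(methods))
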