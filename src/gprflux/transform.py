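"""Compilation of GPR associations into an extended stoichiometric matrix.

The transformation turns Boolean gene states into real-valued fluxes.  Every
reversible reaction is decomposed into forward/backward sub-reactions and
every GPR-bearing reaction is duplicated once per alternative enzyme (DNF
term).  Each gene contributes a pseudo-species that is consumed by the
sub-reactions its product catalyzes (at its subunit copy number) and produced
by a dedicated *enzyme usage* reaction ``u_gene``.  In block form the
extended matrix is

    S' = [[S,     0 ],      v' = [v; u],    ub' = [ub; +inf]
          [S_gpr, I_k]]

where ``S_gpr`` holds -copy_number entries for gene participation and
``I_k`` is the identity over the k usage reactions.  At steady state the
usage flux of a gene equals the total flux carried by its enzyme(s):
``u_i = sum_j copy(i,j) * v_j``.  The extended model contains no additional
constraints, so any constraint-based method applies to it unchanged — its
solutions simply gain a gene-level layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, Metabolite, ModelError, Reaction

__all__ = [
    "ExtendedModel",
    "FluxSolution",
    "GeneLevelSolution",
    "SubReaction",
    "transform_model",
    "split_directions",
    "remove_blocked",
    "collapse_solution",
    "apply_gene_constraints",
]

USAGE_PREFIX = "u_"
SPECIES_PREFIX = "enz_"
BLOCKED_TOL = 1e-9


@dataclass(frozen=True)
class SubReaction:
    """Mapping entry linking a sub-reaction to its parent reaction."""

    id: str
    parent: str
    direction: str  # "fwd" | "bwd"
    enzyme_index: int | None  # index into parent GPR DNF, None if no GPR


@dataclass
class FluxSolution:
    """Reaction-level flux assignment (mmol/gDW/h)."""

    fluxes: dict
    objective_value: float | None = None

    def __getitem__(self, rid):
        return self.fluxes[rid]


@dataclass
class GeneLevelSolution:
    """Gene-level flux assignment: sub-reaction fluxes plus enzyme usages."""

    sub_fluxes: dict
    usage: dict
    objective_value: float | None = None

    def __getitem__(self, rid):
        return self.sub_fluxes[rid]


@dataclass
class ExtendedModel:
    """The transformed model plus bidirectional maps to the original."""

    base: MetabolicModel
    source: MetabolicModel
    gene_species: dict = field(default_factory=dict)  # gene -> species id
    usage_reactions: dict = field(default_factory=dict)  # gene -> reaction id
    split_map: dict = field(default_factory=dict)  # orig rid -> [SubReaction]
    parent_of: dict = field(default_factory=dict)  # sub rid -> orig rid
    copy_numbers: dict = field(default_factory=dict)  # (gene, sub rid) -> int

    @property
    def genes(self) -> list:
        return sorted(self.usage_reactions)

    @property
    def objective(self) -> str | None:
        return self.source.objective

    def gene_of_usage(self, rid: str) -> str | None:
        return rid[len(USAGE_PREFIX):] if rid in set(self.usage_reactions.values()) else None

    def copy(self) -> "ExtendedModel":
        return ExtendedModel(
            base=self.base.copy(), source=self.source,
            gene_species=dict(self.gene_species),
            usage_reactions=dict(self.usage_reactions),
            split_map={k: list(v) for k, v in self.split_map.items()},
            parent_of=dict(self.parent_of),
            copy_numbers=dict(self.copy_numbers),
        )

    def mapping_table(self):
        """Sidecar mapping as a pandas DataFrame
        (sub_reaction, parent, direction, enzyme_index, genes)."""
        import pandas as pd

        rows = []
        for rid, subs in self.split_map.items():
            for sub in subs:
                genes = sorted(g for (g, srid) in self.copy_numbers if srid == sub.id)
                rows.append({
                    "sub_reaction": sub.id, "parent": rid,
                    "direction": sub.direction,
                    "enzyme_index": -1 if sub.enzyme_index is None else sub.enzyme_index,
                    "genes": ";".join(genes),
                })
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        return (f"<ExtendedModel of {self.source.id}: "
                f"{len(self.base.reactions)} reactions, "
                f"{len(self.base.metabolites)} species, "
                f"{len(self.usage_reactions)} genes>")


def _directions(rxn: Reaction) -> list:
    """Decompose bounds into nonnegative (direction, lb, ub) parts."""
    out = []
    if rxn.upper_bound > 0:
        out.append(("fwd", max(rxn.lower_bound, 0.0), rxn.upper_bound))
    if rxn.lower_bound < 0:
        out.append(("bwd", max(-rxn.upper_bound, 0.0), -rxn.lower_bound))
    if not out:  # lb == ub == 0
        out.append(("fwd", 0.0, 0.0))
    return out


def transform_model(
    model: MetabolicModel,
    split_all_reversible: bool = True,
    copy_number_table: dict | None = None,
) -> ExtendedModel:
    """Compile a model's GPRs into its extended stoichiometric form.

    Parameters
    ----------
    model:
        Source model with parsed GPR associations.
    split_all_reversible:
        When True (default) every reversible reaction is direction-split,
        GPR-bearing or not; when False only GPR-bearing ones are (their
        sub-reactions must be nonnegative for gene coupling to make sense).
    copy_number_table:
        Optional ``(gene, reaction_id) -> copies`` overrides for subunit
        stoichiometry; defaults to the copy numbers implied by the GPR
        (1 unless a gene repeats within an AND-clause).
    """
    base = MetabolicModel(model.id + "_ext")
    for met in model.metabolites.values():
        base.add_metabolite(Metabolite(met.id, met.compartment, met.is_external, met.name))

    ext = ExtendedModel(base=base, source=model)
    genes = model.genes
    for g in genes:
        sid = SPECIES_PREFIX + g
        if sid in model.metabolites:
            raise ModelError(f"gene species id {sid!r} collides with a metabolite")
        base.add_metabolite(Metabolite(sid, compartment="pseudo"))
        ext.gene_species[g] = sid

    for rxn in model.reactions.values():
        enzymes = list(rxn.gpr.dnf) if rxn.gpr is not None else [None]
        split = rxn.reversible and (split_all_reversible or rxn.gpr is not None)
        dirs = _directions(rxn) if split else [(None, rxn.lower_bound, rxn.upper_bound)]
        subs = []
        for direction, lb, ub in dirs:
            for idx, enz in enumerate(enzymes):
                sub_id = rxn.id
                if len(enzymes) > 1:
                    sub_id += f"__enz{idx}"
                if direction is not None:
                    sub_id += f"__{direction}"
                stoich = dict(rxn.stoichiometry)
                if direction == "bwd":
                    stoich = {m: -c for m, c in stoich.items()}
                if enz is not None:
                    for g, copies in enz.subunits.items():
                        if copy_number_table is not None:
                            copies = copy_number_table.get((g, rxn.id), copies)
                        stoich[ext.gene_species[g]] = stoich.get(ext.gene_species[g], 0.0) - copies
                        ext.copy_numbers[(g, sub_id)] = copies
                base.add_reaction(Reaction(sub_id, stoich, lb, ub, gpr=None, name=rxn.name))
                subs.append(SubReaction(sub_id, rxn.id,
                                        direction or "fwd",
                                        idx if enz is not None else None))
                ext.parent_of[sub_id] = rxn.id
        ext.split_map[rxn.id] = subs

    for g in genes:
        rid = USAGE_PREFIX + g
        if rid in base.reactions:
            raise ModelError(f"usage reaction id {rid!r} collides with a reaction")
        base.add_reaction(Reaction(rid, {ext.gene_species[g]: 1.0},
                                   0.0, math.inf, gpr=None, name=f"usage of {g}"))
        ext.usage_reactions[g] = rid

    base.medium = dict(model.medium)
    return ext


def split_directions(model: MetabolicModel) -> ExtendedModel:
    """Direction-split a model without gene coupling (all fluxes >= 0).

    Useful for elementary-mode computation on reaction-level networks; the
    result reuses the :class:`ExtendedModel` mapping machinery with an empty
    gene layer.
    """
    stripped = model.copy()
    for rxn in stripped.reactions.values():
        rxn.gpr = None
    return transform_model(stripped)


def remove_blocked(model: MetabolicModel, medium: dict | None = None,
                   tol: float = BLOCKED_TOL) -> MetabolicModel:
    """Drop reactions that can carry no flux under the given medium.

    Blocked reactions are found by flux variability analysis over the whole
    feasible space (no growth requirement): a reaction whose FVA minimum and
    maximum are both within ``tol`` of zero is removed, and metabolites left
    without any reaction are dropped with it.
    """
    from .simulate import fva  # local import to avoid a cycle

    work = model.copy()
    if medium is not None:
        work.apply_medium(medium)
    ranges = fva(work, growth_fraction=None)
    out = MetabolicModel(model.id)
    kept = [rid for rid, (lo, hi) in ranges.items()
            if abs(lo) > tol or abs(hi) > tol]
    used_mets: set = set()
    for rid in kept:
        used_mets |= set(work.reactions[rid].stoichiometry)
    for met in work.metabolites.values():
        if met.id in used_mets:
            out.add_metabolite(Metabolite(met.id, met.compartment, met.is_external, met.name))
    for rid in kept:
        out.add_reaction(work.reactions[rid].copy())
    if model.objective in out.reactions:
        out.objective = model.objective
    elif model.objective is not None:
        raise ModelError("objective reaction is blocked under the given medium")
    out.medium = {k: v for k, v in work.medium.items() if k in out.reactions}
    return out


def collapse_solution(ext: ExtendedModel, sol: GeneLevelSolution) -> FluxSolution:
    """Project an extended-model solution back onto the original reactions:
    net flux = sum of forward sub-fluxes minus sum of backward sub-fluxes,
    summed over isozyme copies."""
    for rid in sol.sub_fluxes:
        if rid not in ext.parent_of and rid not in set(ext.usage_reactions.values()):
            raise KeyError(f"unknown sub-reaction id {rid!r}")
    fluxes = {}
    for rid, subs in ext.split_map.items():
        total = 0.0
        for sub in subs:
            v = sol.sub_fluxes.get(sub.id, 0.0)
            total += v if sub.direction == "fwd" else -v
        fluxes[rid] = total
    return FluxSolution(fluxes=fluxes, objective_value=sol.objective_value)


def apply_gene_constraints(ext: ExtendedModel, constraints: dict) -> ExtendedModel:
    """Return a copy of the extended model with usage-reaction bounds replaced.

    ``constraints`` maps gene id -> (lb, ub); a knockout is ``(0, 0)``.
    """
    new = ext.copy()
    for gene, (lb, ub) in constraints.items():
        if gene not in new.usage_reactions:
            raise ModelError(f"unknown gene {gene!r}")
        if lb > ub:
            raise ModelError(f"gene {gene!r}: lb {lb} > ub {ub}")
        rxn = new.base.reactions[new.usage_reactions[gene]]
        rxn.lower_bound = float(lb)
        rxn.upper_bound = float(ub)
    return new


def check_gene_balance(ext: ExtendedModel, sol: GeneLevelSolution) -> float:
    """Largest violation of ``u_i = sum_j copy(i,j) v_j`` across genes."""
    worst = 0.0
    for g, urid in ext.usage_reactions.items():
        total = sum(copies * sol.sub_fluxes.get(srid, 0.0)
                    for (gg, srid), copies in ext.copy_numbers.items() if gg == g)
        worst = max(worst, abs(sol.usage.get(g, 0.0) - total))
    return worst


def extended_matrix(ext: ExtendedModel):
    """Dense S' with row/column ids (metabolite rows first, then gene rows;
    usage columns last)."""
    S, mets, rxns = ext.base.stoichiometric_matrix()
    usage = set(ext.usage_reactions.values())
    order = [r for r in rxns if r not in usage] + [r for r in rxns if r in usage]
    gene_rows = set(ext.gene_species.values())
    row_order = [m for m in mets if m not in gene_rows] + [m for m in mets if m in gene_rows]
    ridx = {r: i for i, r in enumerate(rxns)}
    midx = {m: i for i, m in enumerate(mets)}
    S2 = S[np.ix_([midx[m] for m in row_order], [ridx[r] for r in order])]
    return S2, row_order, order
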