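"""Metabolic model containers and readers/writers.

Supports SBML Level 3 with the fbc (v2) package as the primary on-disk
format, legacy COBRA-style SBML notes for reading, and a compact
tab-separated fixture format for tests and toy models.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .gpr import GPRAssociation, parse_gpr

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "read_sbml",
    "write_sbml",
    "read_tabular_model",
    "write_tabular_model",
]

DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for structurally invalid models or unreadable files."""


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    is_external: bool = False
    name: str = ""


@dataclass
class Reaction:
    """A reaction: stoichiometry (metabolite id -> coefficient, mmol basis),
    flux bounds in mmol/gDW/h, and an optional GPR association."""

    id: str
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRAssociation | None = None
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Exchanges are identified structurally: a single participating
        metabolite (id prefixes vary across model dialects)."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset:
        return self.gpr.genes if self.gpr is not None else frozenset()

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            name=self.name,
        )


class MetabolicModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    metabolites : dict[str, Metabolite]
    reactions : dict[str, Reaction]
    objective : str | None
        Id of the objective (growth) reaction.
    medium : dict[str, float]
        Exchange-reaction id -> maximal uptake rate (positive number,
        mmol/gDW/h).  Applied to the uptake direction of each exchange.
    """

    def __init__(self, model_id: str = "model"):
        self.id = model_id
        self.metabolites: dict = {}
        self.reactions: dict = {}
        self.objective: str | None = None
        self.medium: dict = {}

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelError(f"reaction {rxn.id!r}: lower bound exceeds upper bound")
        for met in rxn.stoichiometry:
            if met not in self.metabolites:
                self.add_metabolite(Metabolite(met))
        self.reactions[rxn.id] = rxn
        return rxn

    # -- derived ----------------------------------------------------------

    @property
    def genes(self) -> list:
        """Sorted registry of all genes referenced by any GPR (each exactly once)."""
        out: set = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return sorted(out)

    @property
    def exchanges(self) -> list:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def reactions_of_gene(self, gene: str) -> list:
        return [r.id for r in self.reactions.values() if gene in r.genes]

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions) as a numpy array, with row/col ids."""
        import numpy as np

        mets = list(self.metabolites)
        rxns = list(self.reactions)
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for m, coef in self.reactions[rid].stoichiometry.items():
                S[midx[m], j] = coef
        return S, mets, rxns

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id)
        m.metabolites = {k: Metabolite(v.id, v.compartment, v.is_external, v.name)
                         for k, v in self.metabolites.items()}
        m.reactions = {k: v.copy() for k, v in self.reactions.items()}
        m.objective = self.objective
        m.medium = dict(self.medium)
        return m

    def validate(self) -> None:
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelError(f"objective reaction {self.objective!r} not in model")
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id!r}: lb > ub")
            if not rxn.stoichiometry:
                raise ModelError(f"reaction {rxn.id!r}: empty stoichiometry")

    def apply_medium(self, medium: dict | None = None) -> None:
        """Constrain exchange uptake bounds.  All exchanges not listed keep
        their secretion direction but have uptake closed."""
        medium = dict(self.medium if medium is None else medium)
        for rid in self.exchanges:
            rxn = self.reactions[rid]
            coef = next(iter(rxn.stoichiometry.values()))
            imports_forward = coef > 0  # forward flux produces the metabolite
            uptake = medium.get(rid)
            if imports_forward:
                rxn.upper_bound = 0.0 if uptake is None else float(uptake)
            else:
                rxn.lower_bound = 0.0 if uptake is None else -float(uptake)
        self.medium = medium

    def __repr__(self) -> str:
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, {len(self.genes)} genes>")


# ---------------------------------------------------------------------------
# tabular fixture format
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->")


def _parse_side(side: str) -> dict:
    out: dict = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 2:
            coef, met = float(parts[0]), parts[1]
        elif len(parts) == 1:
            coef, met = 1.0, parts[0]
        else:
            raise ModelError(f"cannot parse equation term {term!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_equation(eq: str) -> tuple:
    """Parse ``"2 A + B --> C"`` into (stoichiometry, reversible)."""
    for arrow in _ARROWS:
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            stoich: dict = {}
            for met, coef in _parse_side(left).items():
                stoich[met] = stoich.get(met, 0.0) - coef
            for met, coef in _parse_side(right).items():
                stoich[met] = stoich.get(met, 0.0) + coef
            stoich = {m: c for m, c in stoich.items() if c != 0.0}
            return stoich, arrow == "<=>"
    raise ModelError(f"equation {eq!r} has no arrow ('-->' or '<=>')")


def read_tabular_model(path, model_id: str | None = None) -> MetabolicModel:
    """Read the tab-separated fixture format.

    Columns: ``id  equation  lb  ub  gpr`` (lb/ub/gpr optional; empty fields
    fall back to arrow-implied bounds).  Directive lines::

        @objective <TAB> reaction_id
        @medium <TAB> exchange_id <TAB> uptake_value

    Lines starting with ``#`` are comments.
    """
    model = MetabolicModel(model_id or str(path))
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].startswith("@"):
                directive = fields[0][1:].strip().lower()
                if directive == "objective":
                    model.objective = fields[1].strip()
                elif directive == "medium":
                    model.medium[fields[1].strip()] = float(fields[2])
                else:
                    raise ModelError(f"line {lineno}: unknown directive {fields[0]!r}")
                continue
            fields += [""] * (5 - len(fields))
            rid, eq, lb_s, ub_s, gpr_s = (f.strip() for f in fields[:5])
            if rid in model.reactions:
                raise ModelError(f"line {lineno}: duplicate reaction id {rid!r}")
            stoich, reversible = parse_equation(eq)
            lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_s) if ub_s else DEFAULT_BOUND
            if not reversible and lb < 0:
                raise ModelError(
                    f"line {lineno}: irreversible arrow contradicts lb={lb}"
                )
            model.add_reaction(
                Reaction(rid, stoich, lb, ub, gpr=parse_gpr(gpr_s), name=rid)
            )
    model.validate()
    return model


def write_tabular_model(model: MetabolicModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if model.objective:
            fh.write(f"@objective\t{model.objective}\n")
        for rid, uptake in model.medium.items():
            fh.write(f"@medium\t{rid}\t{uptake:g}\n")
        for rxn in model.reactions.values():
            subs = " + ".join(
                (f"{-c:g} {m}" if c != -1 else m)
                for m, c in rxn.stoichiometry.items() if c < 0
            )
            prods = " + ".join(
                (f"{c:g} {m}" if c != 1 else m)
                for m, c in rxn.stoichiometry.items() if c > 0
            )
            arrow = "<=>" if rxn.reversible else "-->"
            gpr = str(rxn.gpr) if rxn.gpr is not None else ""
            fh.write(f"{rxn.id}\t{subs} {arrow} {prods}\t{rxn.lower_bound:g}"
                     f"\t{rxn.upper_bound:g}\t{gpr}\n")


# ---------------------------------------------------------------------------
# SBML (L3 + fbc v2 primary; legacy COBRA notes read-only)
# ---------------------------------------------------------------------------

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sanitize_sid(raw: str) -> str:
    sid = _SID_BAD.sub("_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    return sid


def _fbc_association_to_string(assoc) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_fbc_association_to_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_fbc_association_to_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelError(f"unsupported fbc association node {assoc!r}")


_NOTES_GPR = re.compile(r"GENE[ _]ASSOCIATION:\s*([^<]+)", re.IGNORECASE)


def read_sbml(path, require_objective: bool = True) -> MetabolicModel:
    """Read an SBML model (L3+fbc v2 preferred, legacy notes GPRs supported).

    GPR strings are parsed with :func:`gprflux.gpr.parse_gpr`; a reaction with
    an unparsable GPR raises an error naming the reaction.  Gene identifiers
    are fbc geneProduct labels where available, ids otherwise.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise ModelError(f"cannot read SBML file {path}")
    sbml_model = doc.getModel()
    model = MetabolicModel(sbml_model.getId() or str(path))

    fbc = sbml_model.getPlugin("fbc")
    gene_names = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(Metabolite(
            id=sp.getId(),
            compartment=sp.getCompartment() or "c",
            is_external=bool(sp.getBoundaryCondition()),
            name=sp.getName() or "",
        ))

    def parameter_value(pid):
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    any_gpr = False
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict = {}
        for j in range(rxn.getNumReactants()):
            sr = rxn.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            sr = rxn.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()

        lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        ub = DEFAULT_BOUND
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            v = parameter_value(rfbc.getLowerFluxBound())
            if v is not None:
                lb = v
        if rfbc is not None and rfbc.isSetUpperFluxBound():
            v = parameter_value(rfbc.getUpperFluxBound())
            if v is not None:
                ub = v
        kl = rxn.getKineticLaw()
        if kl is not None:
            for pid, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = kl.getParameter(pid)
                if p is not None:
                    if setter == "lb":
                        lb = p.getValue()
                    else:
                        ub = p.getValue()

        gpr_text = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            raw = _fbc_association_to_string(assoc)
            for gid, label in gene_names.items():
                raw = re.sub(rf"\b{re.escape(gid)}\b", label, raw)
            gpr_text = raw
        elif rxn.isSetNotes():
            m = _NOTES_GPR.search(rxn.getNotesString())
            if m:
                gpr_text = m.group(1).strip()
        try:
            gpr = parse_gpr(gpr_text)
        except Exception as exc:
            raise ModelError(f"reaction {rxn.getId()!r}: unparsable GPR: {exc}") from exc
        if gpr is not None:
            any_gpr = True
        model.add_reaction(Reaction(
            id=rxn.getId(), stoichiometry=stoich, lower_bound=lb,
            upper_bound=ub, gpr=gpr, name=rxn.getName() or "",
        ))

    # objective: fbc active objective, falling back to legacy OBJECTIVE_COEFFICIENT
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(fbc.getActiveObjectiveId() or 0) or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = obj.getFluxObjective(0).getReaction()
    if model.objective is None:
        for i in range(sbml_model.getNumReactions()):
            rxn = sbml_model.getReaction(i)
            kl = rxn.getKineticLaw()
            if kl is not None:
                p = kl.getParameter("OBJECTIVE_COEFFICIENT")
                if p is not None and p.getValue() != 0:
                    model.objective = rxn.getId()
                    break
    if model.objective is None and require_objective:
        raise ModelError(f"no objective reaction found in {path}")
    if not any_gpr:
        logger.warning("model %s contains no GPR associations", model.id)
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Write SBML L3v1 + fbc v2.  Extended models (pure stoichiometry with
    gene pseudo-species as ordinary species) serialize like any other model;
    a round trip reproduces stoichiometry, bounds and objective exactly."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = {m.compartment for m in model.metabolites.values()} or {"c"}
    for cid in sorted(compartments):
        comp = sbml_model.createCompartment()
        comp.setId(_sanitize_sid(cid))
        comp.setConstant(True)
        comp.setSize(1.0)

    sid_of_met = {}
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sid = _sanitize_sid(met.id)
        sid_of_met[met.id] = sid
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize_sid(met.compartment))
        sp.setBoundaryCondition(met.is_external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    # shared flux-bound parameters
    bound_params: dict = {}

    def bound_param(value: float) -> str:
        key = value
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value) if math.isfinite(value) else
                       (1e9 if value > 0 else -1e9))
            if not math.isfinite(value):
                p.setValue(float("inf") if value > 0 else float("-inf"))
            p.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(_sanitize_sid(rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
                sr.setSpecies(sid_of_met[met])
                sr.setStoichiometry(-coef)
            else:
                sr = r.createProduct()
                sr.setSpecies(sid_of_met[met])
                sr.setStoichiometry(coef)
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            # libsbml parses the infix and auto-creates geneProducts whose
            # labels are the gene names used here
            infix = " or ".join(
                "(" + " and ".join(sorted(enz.genes)) + ")"
                for enz in rxn.gpr.dnf
            )
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(infix)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize_sid(model.objective))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"failed to write SBML to {path}")
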