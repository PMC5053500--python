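"""Deterministic toy models and seeded random model generation.

The toys cover the GPR association types that make gene-level analysis
differ from reaction-level analysis: isozymes, multi-subunit complexes,
promiscuous (shared-subunit) enzymes, and a growth-coupled production
network for strain-design and sampling studies.  The random generator
emulates the GPR complexity observed in curated genome-scale
reconstructions — complexes of up to 13 subunits, up to 7 isozymes per
reaction, and a heavy-tailed distribution of reactions per enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpr import parse_gpr
from .model import MetabolicModel, ModelError, Reaction

__all__ = ["GPRComplexityProfile", "toy_models", "random_model"]


@dataclass
class GPRComplexityProfile:
    """Knobs bounding generated GPR complexity (all >= 1)."""

    max_subunits: int = 13
    max_isozymes: int = 7
    promiscuity_tail: float = 2.0  # zipf exponent for gene reuse
    no_gpr_fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.max_subunits < 1 or self.max_isozymes < 1:
            raise ModelError("complexity bounds must be >= 1")


def _rxn(model, rid, eq, lb=None, ub=None, gpr=""):
    from .model import parse_equation

    stoich, reversible = parse_equation(eq)
    lb = (-1000.0 if reversible else 0.0) if lb is None else lb
    ub = 1000.0 if ub is None else ub
    model.add_reaction(Reaction(rid, stoich, lb, ub, gpr=parse_gpr(gpr)))


def _gpr_showcase() -> MetabolicModel:
    """All three GPR association types in one small network."""
    m = MetabolicModel("gpr_showcase")
    _rxn(m, "EX_A", " --> A", 0, 10)
    _rxn(m, "r_iso", "A --> B", gpr="g1 or g2")
    _rxn(m, "r_cplx", "B --> C", gpr="g3 and g4")
    _rxn(m, "r_prom1", "C --> D", gpr="g5")
    _rxn(m, "r_prom2", "C --> E", gpr="g5")
    _rxn(m, "EX_D", "D --> ")
    _rxn(m, "EX_E", "E --> ")
    m.objective = "EX_D"
    return m


def _efm_toy() -> MetabolicModel:
    """Linear pathway whose middle step has two isozymes: one EFM before
    transformation, two gene-annotated EFMs after."""
    m = MetabolicModel("efm_toy")
    _rxn(m, "r1", " --> A", 0, 10)
    _rxn(m, "r2", "A --> B", gpr="gx")
    _rxn(m, "r3", "B --> C", gpr="gy or gz")
    _rxn(m, "r4", "C --> ")
    m.objective = "r4"
    return m


def _two_isozyme() -> MetabolicModel:
    """One reaction catalyzed by a 5-subunit complex or a monomer: the
    canonical case where enzyme-usage minimization prefers the monomer."""
    m = MetabolicModel("two_isozyme")
    _rxn(m, "EX_S", " --> S", 0, 10)
    _rxn(m, "r_cat", "S --> P", gpr="(c1 and c2 and c3 and c4 and c5) or m1")
    _rxn(m, "r_bio", "P --> ")
    m.objective = "r_bio"
    return m


def _lpd_like() -> MetabolicModel:
    """A shared enzyme subunit (gene L) participating in two reactions, one
    of which has a 3-subunit isozyme: down-regulating L triggers a staged,
    non-linear redistribution of flux across the reactions it serves."""
    m = MetabolicModel("lpd_like")
    _rxn(m, "EX_S", " --> S", 0, 10)
    _rxn(m, "r1", "S --> P1", gpr="(a1 and L) or (i1 and i2 and i3)")
    _rxn(m, "r2", "S --> P2", gpr="a2 and L")
    _rxn(m, "growth", "P1 + P2 --> ")
    m.objective = "growth"
    return m


def _branched() -> MetabolicModel:
    """Fermentation-style network with a redox couple: glycolysis produces
    reducing equivalents (N) that must leave through the ethanol branch,
    the lactate-like byproduct branch, or respiration.  Closing respiration
    and deleting the byproduct branch growth-couples ethanol production."""
    m = MetabolicModel("branched")
    _rxn(m, "r_up", " --> G", 0, 10)
    _rxn(m, "r_gly", "G --> 2 P + N", gpr="gA")
    _rxn(m, "r_eth", "P + N --> E", gpr="gE1 or gE2")
    _rxn(m, "r_lac", "P + N --> L", gpr="gL")
    _rxn(m, "r_resp", "N --> ", gpr="gR")
    _rxn(m, "r_bio", "P --> ")
    _rxn(m, "EX_E", "E --> ")
    _rxn(m, "EX_L", "L --> ")
    m.objective = "r_bio"
    return m


def _promiscuity_trap() -> MetabolicModel:
    """Same network, but the byproduct gene gL moonlights as a glycolysis
    complex subunit: the naive gene translation of the reaction-based design
    (delete the byproduct branch) silently kills growth."""
    m = _branched()
    m.id = "promiscuity_trap"
    m.reactions["r_gly"].gpr = parse_gpr("gA and gL")
    return m


def toy_models() -> dict:
    """Fresh copies of all named toy fixtures."""
    return {
        "gpr_showcase": _gpr_showcase(),
        "efm_toy": _efm_toy(),
        "two_isozyme": _two_isozyme(),
        "lpd_like": _lpd_like(),
        "branched": _branched(),
        "promiscuity_trap": _promiscuity_trap(),
    }


def random_model(profile: GPRComplexityProfile | None = None,
                 n_reactions: int = 10, seed: int | None = None,
                 max_retries: int = 20) -> MetabolicModel:
    """Seeded random growth-feasible model with profile-bounded GPRs.

    A linear backbone from substrate uptake to a growth sink guarantees
    feasibility; extra reactions add branches (some reversible).  Gene
    identifiers are reused across reactions with a heavy-tailed (zipf)
    distribution, generating promiscuous enzymes.
    """
    if n_reactions < 3:
        raise ModelError("need at least 3 reactions")
    profile = profile or GPRComplexityProfile()
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        m = MetabolicModel(f"random_{seed}_{attempt}")
        n_chain = max(2, (n_reactions - 2) // 2)
        _rxn(m, "r_up", " --> M0", 0, 10)
        pool_size = max(4, 2 * n_reactions)

        def draw_gpr():
            if rng.random() < profile.no_gpr_fraction:
                return ""
            n_iso = 1 + min(rng.geometric(0.6) - 1, profile.max_isozymes - 1)
            enzymes = []
            for _ in range(n_iso):
                n_sub = 1 + min(rng.geometric(0.5) - 1, profile.max_subunits - 1)
                genes = set()
                while len(genes) < n_sub:
                    idx = min(int(rng.zipf(profile.promiscuity_tail)), pool_size) - 1
                    genes.add(f"g{idx}")
                enzymes.append("(" + " and ".join(sorted(genes)) + ")")
            return " or ".join(enzymes)

        for i in range(1, n_chain + 1):
            _rxn(m, f"rc{i}", f"M{i-1} --> M{i}", gpr=draw_gpr())
        n_extra = n_reactions - n_chain - 2
        for e in range(max(0, n_extra)):
            i, j = sorted(rng.choice(n_chain + 1, size=2, replace=False))
            rev = rng.random() < 0.3
            # consuming-side coefficients (1:1 when reversible) keep fluxes
            # at uptake scale in both directions, so the default internal
            # bounds never bind
            coef = 1 if rev else int(rng.integers(1, 3))
            eq = f"{coef} M{i} {'<=>' if rev else '-->'} M{j}"
            _rxn(m, f"rx{e}", eq, gpr=draw_gpr())
        _rxn(m, "r_growth", f"M{n_chain} --> ")
        m.objective = "r_growth"

        from .simulate import fba

        if fba(m).optimal and (fba(m).objective_value or 0) > 1e-6:
            return m
    raise ModelError("could not draw a growth-feasible model")
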