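#!/usr/bin/env python
"""Genome-scale reproduction on the published iAF1260 E. coli model.

Requires a locally downloaded iAF1260 SBML file (e.g. from the BiGG model
repository); nothing is fetched over the network.  Reports:

  * GPR complexity statistics: fraction of reactions with multiple
    isozymes, fraction catalyzed by at least one promiscuous enzyme,
    fraction of multi-subunit enzymes;
  * model size after blocked-reaction removal under aerobic glucose
    minimal medium (genes / reactions / metabolites);
  * extended-matrix size after the GPR transformation
    (pseudo-reactions / pseudo-metabolites);
  * the reactions with the largest numbers of minimal gene-deletion
    combinations (multi-complex isozymes such as FHL, PTS, ATP synthase).

Usage::

    python scripts/reproduce_iaf1260.py path/to/iAF1260.xml
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import gprflux as gf  # noqa: E402
from gprflux.gpr import CapacityError  # noqa: E402


def gpr_statistics(model):
    with_gpr = [r for r in model.reactions.values() if r.gpr is not None]
    multi_iso = sum(1 for r in with_gpr if len(r.gpr.dnf) > 1)
    enzymes = {e for r in with_gpr for e in r.gpr.dnf}
    multi_subunit = sum(1 for e in enzymes if len(e.genes) > 1)
    catalyzes = {}
    for r in with_gpr:
        for e in r.gpr.dnf:
            catalyzes.setdefault(e, set()).add(r.id)
    promiscuous_enzymes = {e for e, rids in catalyzes.items() if len(rids) > 1}
    prom_rxns = sum(1 for r in with_gpr
                    if any(e in promiscuous_enzymes for e in r.gpr.dnf))
    return {
        "reactions_with_gpr": len(with_gpr),
        "multi_isozyme_fraction": multi_iso / len(with_gpr),
        "promiscuous_reaction_fraction": prom_rxns / len(with_gpr),
        "multi_subunit_enzyme_fraction": multi_subunit / len(enzymes),
        "max_subunits": max(len(e.genes) for e in enzymes),
        "max_isozymes": max(len(r.gpr.dnf) for r in with_gpr),
    }


def main(path):
    model = gf.read_sbml(path)
    print(f"loaded: {model}")
    stats = gpr_statistics(model)
    for k, v in stats.items():
        print(f"  {k}: {v:.3f}" if isinstance(v, float) else f"  {k}: {v}")

    print("removing blocked reactions (FVA, default medium as shipped)...")
    simplified = gf.remove_blocked(model)
    print(f"  simplified: {len(simplified.genes)} genes, "
          f"{len(simplified.reactions)} reactions, "
          f"{len(simplified.metabolites)} metabolites")

    ext = gf.transform_model(simplified)
    print(f"  extended: {len(ext.base.reactions)} (pseudo-)reactions, "
          f"{len(ext.base.metabolites)} (pseudo-)metabolites")

    print("largest minimal gene-deletion combination counts per reaction:")
    counts = []
    for r in simplified.reactions.values():
        if r.gpr is None:
            continue
        try:
            counts.append((len(gf.minimal_knockout_sets(r.gpr, cap=50_000)), r.id))
        except CapacityError:
            continue
    for n, rid in sorted(counts, reverse=True)[:10]:
        print(f"  {rid}: {n}")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        print(__doc__)
        sys.exit(2)
    main(sys.argv[1])
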