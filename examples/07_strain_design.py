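"""Growth-coupled strain design: reaction vs gene cut sets.

Anaerobically, deleting the lactate-like branch couples ethanol yield to
growth in the fermentation toy.  Expanding that reaction design to gene
deletions is safe only when the genes are dedicated: in the promiscuity
trap the byproduct gene also serves a glycolysis complex, and the audit
shows the naive gene design kills growth.  Enumerating on the transformed
model returns gene designs whose side effects are accounted for upfront.
"""

import gprflux as gf

scenario = gf.ProductionScenario(substrate="r_up", product="EX_E",
                                 mu_min=0.001, y_min=0.8,
                                 extra_bounds={"r_resp": (0.0, 0.0)})

m = gf.toy_models()["branched"]
targets = [r.id for r in m.reactions.values() if r.gpr is not None]
rdesigns = gf.enumerate_cut_sets(m, scenario, targets, max_size=1)
print("reaction-based cut sets:", [sorted(d.targets) for d in rdesigns])

ext = gf.transform_model(m)
gdesigns = gf.enumerate_cut_sets(ext, scenario, ext.genes, max_size=1)
print("gene-based cut sets (extended model):",
      [sorted(d.targets) for d in gdesigns])

trap = gf.toy_models()["promiscuity_trap"]
rtrap = gf.enumerate_cut_sets(trap, scenario,
                              [r.id for r in trap.reactions.values()
                               if r.gpr is not None], max_size=1)
naive = gf.expand_to_gene_designs(rtrap[0], trap)
audit = gf.validate_design(naive[0], trap, scenario)
print(f"\npromiscuity trap: reaction design {sorted(rtrap[0].targets)} "
      f"-> gene design {sorted(naive[0].targets)}")
print(f"  effective reaction deletions: "
      f"{sorted(audit.effective_reaction_deletions)}")
print(f"  feasible: {audit.feasible} "
      "(the shared subunit also kills glycolysis)")

# combinatorics of multi-complex isozymes: 11- and 7-subunit complexes
fhl = gf.parse_gpr("(" + " and ".join(f"a{i}" for i in range(11)) + ") or ("
                   + " and ".join(f"b{i}" for i in range(7)) + ")")
print(f"\ntwo disjoint complexes (11 + 7 subunits): "
      f"{len(gf.minimal_knockout_sets(fhl))} minimal gene-deletion combinations")
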