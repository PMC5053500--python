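"""Gene essentiality by flux variability of the usage variables.

One FVA sweep over the enzyme-usage fluxes at 10% of maximal growth
classifies every gene: a positive minimal usage means the gene is
essential; a zero maximal usage means its enzyme can never carry flux
(a blocked gene).  The ranges themselves are more informative than the
binary verdict of knockout-based testing.
"""

import gprflux as gf

m = gf.toy_models()["branched"]
ext = gf.transform_model(m)
table = gf.gene_essentiality(ext, growth_fraction=0.1)
print(table.round(3))
print("\nessential:", sorted(table.index[table.essential]))
print("blocked:", sorted(table.index[table.blocked]))
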