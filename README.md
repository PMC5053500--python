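# gprflux

Gene-level constraint-based metabolic modeling via stoichiometric
compilation of gene–protein–reaction (GPR) associations.

## The problem

Constraint-based models predict metabolic phenotypes as steady-state flux
distributions, `S·v = 0`, `lb ≤ v ≤ ub`. But the stoichiometric matrix `S`
speaks the language of *reactions*, while perturbations — knockouts,
over-expression, transcript measurements — happen at the level of *genes*.
The two are linked by Boolean GPR rules (`AND` = complex subunits, `OR` =
isozymes), which most methods can only consult after the fact, losing the
effects of isozyme redundancy and enzyme promiscuity.

`gprflux` compiles the GPR rules *into* the stoichiometric matrix. Every
gene becomes a pseudo-species, every alternative enzyme its own
sub-reaction consuming its subunit species, and one artificial *enzyme
usage* reaction `u_i` per gene closes each balance:

```
S' = [[S,     0 ],      v' = [v; u],     ub' = [ub; +∞]
      [S_gpr, I_k]]
```

with `S_gpr` holding `−copy_number` entries for gene participation and
`I_k` the identity over the `k` usage reactions. At steady state
`u_i = Σ_j copy(i,j)·v_j` — the total flux carried by the enzyme(s)
encoded by gene `i`. The transformed model is a plain stoichiometric model
(it serializes to ordinary SBML), so *any* constraint-based method runs on
it unchanged and gains a gene-level layer for free:

* **gene-pFBA** — `min Σ u_i` at maximal growth (parsimonious *enzyme*
  allocation instead of parsimonious flux);
* **gene-MOMA / gene-lMOMA** — `min Σ (u_i − u_i^wt)²` or `Σ |u_i − u_i^wt|`
  with the deleted genes' usages forced to zero;
* **over/under-expression** — bounds `u_i ≥ λ·u_i^wt` (λ>1) or
  `u_i ≤ λ·u_i^wt` (λ<1) on single usage variables;
* **essentiality by FVA** — `min/max u_i` s.t. `v_growth ≥ 0.1·v_growth^max`;
  positive minimum ⇒ essential, zero maximum ⇒ blocked;
* **gene-GIMME / gene-EFlux** — expression penalties/caps applied directly
  to `u` instead of through a lossy AND/OR mapping;
* **gene-annotated elementary flux modes** — usage reactions join each
  mode's support, naming the genes every minimal pathway needs;
* **gene-based minimal cut sets** — enumerate deletions over usage
  reactions, with promiscuity side effects accounted for upfront, plus an
  audit (`validate_design`) that exposes why naive gene translations of
  reaction-based designs fail;
* **gene-level flux sampling** — hit-and-run over the extended polytope,
  comparing usage distributions between phenotypes.

The intended users are systems/metabolic engineers who already work with
genome-scale models (SBML + fbc) and want gene-resolution predictions or
genetically implementable strain designs.

## Worked example

```python
import gprflux as gf

model = gf.toy_models()["two_isozyme"]   # S -> P by a 5-subunit complex OR a monomer
ext = gf.transform_model(model)
res = gf.pfba(ext, level="gene")
print(res.objective_value)               # 10.0  (growth, same as FBA)
print(res.solution.usage["m1"])          # 10.0  (all flux through the monomer)
print(sum(res.solution.usage.values()))  # 10.0  (the complex route would cost 50)
```

Reaction-level pFBA cannot distinguish the two routes — both carry the
same flux — but minimizing enzyme usage prices the complex at 5 gene-units
per flux unit and routes everything through the monomer. The
`examples/` directory holds one short script per capability
(`python examples/02_gene_pfba.py` prints the numbers above, with
neighbors covering transformation, knockouts/modulation, essentiality,
omics integration, elementary modes, strain design and sampling).

Models load from SBML L3+fbc (`read_sbml`) or a tab-separated fixture
format (`read_tabular_model`); a thin `gprflux` CLI wraps the common
workflows (`gprflux simulate --method gene-pfba --model m.xml`, `gprflux
design ...`, `gprflux sample ...`).

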