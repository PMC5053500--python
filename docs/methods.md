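# Methods

## Model and transformation

A metabolic model is a stoichiometric matrix `S` over metabolites and
reactions with flux bounds (mmol/gDW/h) and, per reaction, an optional
Boolean GPR rule over gene identifiers (`AND`/`OR`, parentheses; no
negation). The transformation to the gene level proceeds in three steps:

1. **DNF normalization.** Each GPR is parsed (recursive descent; operators
   case-insensitive, gene ids case-sensitive after trimming) and expanded
   to a minimal disjunctive normal form by distribution with on-the-fly
   absorption and deduplication. Each conjunction is an *enzyme*: a
   multiset of subunit genes. A gene repeated inside one AND-clause gets
   copy number 2 — subunit stoichiometry lives in the coefficients, and a
   user-supplied copy-number table can override the default of 1 (curated
   reconstructions rarely report multimer stoichiometry, so enzyme usage
   of multimers is otherwise underestimated). Expansion is capped
   (default 10,000 terms) and fails loudly rather than truncating:
   genome-scale GPRs are shallow, but adversarial input should not produce
   a silently wrong model.
2. **Decomposition.** Every reversible reaction is split into forward and
   backward sub-reactions with bounds `[0, ub]` and `[0, −lb]` (all
   reversible reactions, not only GPR-bearing ones, so the extended model
   is uniformly nonnegative; a flag restricts splitting to GPR reactions
   for size studies). Every GPR reaction is duplicated once per DNF
   enzyme. Sub-reaction ids are deterministic (`rid__enzN__fwd` with `N`
   the DNF index under lexicographic enzyme ordering), so mappings
   reproduce across runs.
3. **Gene coupling.** Each gene becomes a pseudo-species consumed by its
   enzymes' sub-reactions at the subunit copy number and produced by a
   dedicated usage reaction `u_gene` with bounds `[0, +∞)`. At steady
   state `u_i = Σ_j copy(i,j)·v_j`.

**Bound semantics.** Duplicated sub-reactions each inherit the parent's
bounds: bounds are *per-enzyme capacities* in the decomposed
representation. Consequently the FBA optimum of the extended model equals
the original's whenever GPR-reaction bounds are non-binding — the normal
genome-scale situation, where internal bounds (±1000) sit far above
substrate-limited fluxes and effectively encode reversibility only. The
synthetic-model generator preserves this regime by keeping internal
stoichiometry non-amplifying, and the equality is verified on every
generated fixture to 1e-6.

## Simulation methods

All methods reduce to LPs solved with HiGHS (deterministic) or, for
quadratic MOMA, a convex QP solved with scipy's trust-constr on the
`||P·x − r||²` objective with sparse Hessian — adequate at the problem
sizes this package targets (toys through single genome-scale LPs); the QP
path is a declared solver capability and raises rather than silently
substituting the linear variant. Absolute-value objectives use auxiliary
variables only for columns that can go negative.

* **FBA / pFBA.** pFBA fixes growth at its FBA maximum (equality,
  tolerance limited only by the LP solver) and then minimizes total flux
  (reaction level) or `Σ u_i` (gene level). Every LP-based method also
  exposes an optional second stage minimizing the l1-norm of the flux
  vector at the fixed objective, because optimal-solution degeneracy
  otherwise makes downstream error metrics irreproducible.
* **MOMA / lMOMA.** Deviation from a wild-type reference over usage
  variables (gene level) or net reaction fluxes (reaction level), with
  deletions as zero bounds. The reference defaults to pFBA at the matching
  level — gene-pFBA uniquely prices the usage vector, which a plain FBA
  solution does not. Deleting an essential function returns status
  `infeasible` (the lethality signal), never an exception. Note that with
  a free substrate uptake the minimal adjustment can legitimately be "stop
  eating"; deletion studies should fix the uptake to its measured value,
  as the benchmark harness does.
* **Modulation.** `λ = 1` reproduces the unconstrained optimum; `λ ≤ 0`
  is rejected (a knockout expresses 0 exactly).
* **Essentiality.** FVA of each `u_i` under `v_growth ≥ 0.1·v_growth^max`
  (fraction configurable); essential ⇔ min above 1e-6, blocked ⇔ max at
  most 1e-6. An infeasible baseline raises instead of reporting
  everything essential. This agrees exactly with knockout-then-FBA
  essentiality on all fixtures (tested as set equality).
* **GIMME.** Cutoff = 25th percentile of the measured expression values,
  linear interpolation between order statistics (the method is recorded
  in result metadata since percentile conventions differ). Penalties
  `c_i = cutoff − e_i` for below-cutoff genes on `u_i`; growth fixed at
  85% of maximum as an equality, with a flag for the conventional `≥`
  form. Reaction-level GIMME (the comparator) maps expression through the
  rule with AND→min, OR→sum — the conventional, lossy mapping the
  gene-level variant exists to avoid. Unmeasured genes carry no penalty.
* **E-Flux.** Step 1 caps `u_i ≤ e_i / max(e)` (gene level) or reaction
  fluxes by the mapped score (reaction level), intersected with existing
  bounds so knockouts survive; unmeasured genes are not capped (missing
  data must not constrain). Step 2 rescales the whole vector so the
  substrate uptake equals the measurement — uniform scaling preserves
  `S·v = 0` but may exceed original bounds, which is inherent to the
  method. A zero step-1 uptake is an error, not a zero prediction.

## Elementary modes, cut sets, sampling

* **EFMs** are enumerated by an iterative double-description scheme on the
  direction-split network with the combinatorial (support-minimality)
  adjacency test, coefficients normalized to a maximum of 1, futile
  forward/backward two-cycles discarded. A guard (default 40
  sub-reactions) redirects larger problems to dedicated tools — complete
  enumeration is exponential and this implementation is meant for network
  analysis at desk scale, where it is verified against an exhaustive
  kernel-rank oracle on every network of ≤ 8 reactions.
* **Constrained minimal cut sets** are found by exhaustive subset
  enumeration with superset pruning, which *is* the point at desk scale:
  every verdict is an explicit LP test. The undesired region (growth at
  least μ_min with product yield below Y_min) counts as cut when
  `min (v_product − Y_min·v_substrate)` over growth-compatible states is
  ≥ 0 (tolerance 1e-6) or the region is infeasible outright; the desired
  region (growth plus the yield bound) must remain LP-feasible. The
  default scenario mirrors anaerobic growth-coupled ethanol production
  (μ ≥ 0.001 h⁻¹, Y ≥ 1.4 mol/mol) and is fully configurable. Targeting
  usage reactions on the extended model yields gene designs directly;
  `expand_to_gene_designs` (Cartesian product of per-reaction minimal
  hitting sets, minimized across reactions) and `validate_design`
  (effective reaction deletions via GPR evaluation, then the same two LP
  tests) implement the naive translate-then-audit workflow for
  comparison.
* **Sampling** uses plain hit-and-run in the nullspace of `S` from a
  maximum-slack (Chebyshev-style) interior start, rather than the ACHR
  toolbox variant — simpler, seedable, and the conclusions drawn from the
  samples are distributional, not sampler-specific. Every sample satisfies
  the balances by construction; bounds are enforced on each chord.
  Scenario presets: wild type at ≥ 90% of maximal biomass; producer at
  ≥ 10% biomass and ≥ 90% of the maximal production attainable there
  (inequalities, not equalities). Distribution overlap is histogram
  intersection with Freedman–Diaconis binning on the pooled values —
  "non-overlapping" needs an operational definition and this one is
  scale-free.

## Synthetic fixtures and benchmark

The toy models cover exactly the GPR situations where gene- and
reaction-level analyses diverge: an isozyme pair with asymmetric enzyme
cost (5-subunit complex vs monomer), a shared subunit serving two
reactions with one isozyme backup (staged non-linear modulation
response), a fermentation network with a redox couple whose byproduct
branch growth-couples ethanol when deleted, and a promiscuity trap where
the byproduct gene moonlights in glycolysis so the naive gene design
fails its audit.

The random generator draws connected, growth-feasible networks around a
linear backbone with seeded determinism. GPR complexity is bounded by a
profile whose defaults reflect curated genome-scale reconstructions:
complexes up to 13 subunits, up to 7 isozymes per reaction, heavy-tailed
(zipf, exponent 2) gene reuse producing promiscuous enzymes, and a 20%
fraction of spontaneous/orphan reactions. What the generator does *not*
emulate: realistic currency-metabolite connectivity, compartments,
thermodynamic directionality patterns, or biomass compositions — passing
its property suite demonstrates correctness of the machinery, not
predictive accuracy on real organisms, which is why the genome-scale
script exists separately.

The benchmark metric is `‖v_sim − v_exp‖₁ / ‖v_exp‖₁` over the measured
reactions only. Conditions fix the substrate uptake to its measured
value; deletions are applied at the gene level for gene-wise methods and
as GPR-evaluated reaction deletions for reaction-level methods —
mirroring what each family can express. Errors are reported per condition
and never aggregated.

## Problem sizes and numerical defaults

Defaults throughout: blocked-reaction tolerance 1e-9 on FVA extrema (LP
noise floor), feasibility/essentiality tolerances 1e-6, EFM support
tolerance 1e-9, DNF cap 10,000 terms, knockout-set cap 100,000
candidates, EFM guard 40 sub-reactions, cut-set guard 10⁶ candidate
subsets. The test suite runs its property checks at 1000 random GPRs,
100 random models, and ≤ 8-reaction EFM oracles; these sizes make the
exhaustive oracles exact while keeping the whole suite in seconds.
Sampling defaults to 10,000 samples at thinning 100; the suite uses
smaller draws since its assertions are feasibility and moment checks.

## Known limitations

* Quadratic MOMA relies on a general NLP solver; at genome scale a
  dedicated QP backend would be preferable (interface ready, capability
  flag declared).
* Per-enzyme capacity semantics (above) means optimum equality with the
  original model is conditional on non-binding GPR-reaction bounds.
* EFM and cut-set enumeration are exhaustive by design and desk-scale
  only; genome-scale strain design needs MILP enumeration engines, whose
  problem setup (target regions, targetable sets) this package prepares.
* The hit-and-run sampler has no formal mixing guarantee; fixed seeds
  give reproducibility, not uniformity certificates.
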