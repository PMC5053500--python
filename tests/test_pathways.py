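"""Elementary flux modes, cut-set enumeration, and design validation."""

import numpy as np
import pytest

import gprflux as gf
from gprflux.gpr import CapacityError
from gprflux.model import ModelError
from gprflux.simulate import LinearView

from conftest import brute_force_efm_supports


def anaerobic_scenario(y_min=0.8):
    return gf.ProductionScenario(substrate="r_up", product="EX_E",
                                 mu_min=0.001, y_min=y_min,
                                 extra_bounds={"r_resp": (0.0, 0.0)})


def efm_supports(target):
    return {e.support for e in gf.compute_efms(target)}


class TestEFMs:
    def test_single_linear_pathway_has_one_mode(self, toys):
        modes = gf.compute_efms(toys["efm_toy"])
        assert len(modes) == 1
        assert modes[0].support == frozenset({"r1", "r2", "r3", "r4"})

    def test_isozyme_doubles_modes_with_gene_annotations(self, toys):
        """Transforming the toy splits the isozyme step: each through-mode
        becomes two gene-annotated modes, one per isozyme."""
        ext = gf.transform_model(toys["efm_toy"])
        modes = gf.compute_efms(ext)
        assert len(modes) == 2
        assert {m.gene_support for m in modes} == {
            frozenset({"gx", "gy"}), frozenset({"gx", "gz"})}

    def test_steady_state_and_support_minimality(self, toys):
        for target in (toys["efm_toy"], gf.transform_model(toys["efm_toy"]),
                       toys["branched"]):
            modes = gf.compute_efms(target)
            view = LinearView(target if isinstance(target, gf.ExtendedModel)
                              else target)
            S = view.A.toarray()
            supports = [m.support for m in modes]
            for m in modes:
                v = np.array([m.flux_pattern.get(r, 0.0) for r in view.ids])
                assert np.max(np.abs(S @ v)) <= 1e-9
                assert all(c > 0 for c in m.flux_pattern.values())
                assert not any(s < m.support for s in supports)

    def test_matches_brute_force_oracle(self, toys):
        """Mode supports equal exhaustive enumeration (kernel rank test per
        subset) on every network of at most 8 reactions."""
        targets = [toys["efm_toy"], gf.transform_model(toys["efm_toy"]),
                   toys["branched"], toys["lpd_like"]]
        for seed in (0, 1):
            targets.append(gf.random_model(n_reactions=6, seed=seed))
        for target in targets:
            # the oracle runs on the same direction-split network
            if isinstance(target, gf.ExtendedModel):
                oracle_view = LinearView(target)
            elif any(r.reversible for r in target.reactions.values()):
                oracle_view = LinearView(gf.split_directions(target))
            else:
                oracle_view = LinearView(target)
            if len(oracle_view.ids) > 8:
                continue
            S = oracle_view.A.toarray()
            expected = brute_force_efm_supports(S, oracle_view.ids)
            # drop futile forward/backward two-cycles, which are artifacts
            # of the split and not modes of the original network
            expected = {s for s in expected
                        if not (len(s) == 2
                                and {r.rsplit("__", 1)[-1] for r in s}
                                == {"fwd", "bwd"}
                                and len({r.rsplit("__", 1)[0] for r in s}) == 1)}
            got = efm_supports(target)
            assert got == expected

    def test_reversible_reactions_are_split_first(self):
        m = gf.MetabolicModel("rev")
        m.add_reaction(gf.Reaction("EX_A", {"A": 1.0}, 0, 10))
        m.add_reaction(gf.Reaction("r", {"A": -1.0, "B": 1.0}, -1000, 1000))
        m.add_reaction(gf.Reaction("EX_B", {"B": -1.0}, 0, 1000))
        m.objective = "EX_B"
        modes = gf.compute_efms(m)
        # one through-mode; no spurious fwd/bwd futile cycle
        assert {frozenset(s.support) for s in modes} == {
            frozenset({"EX_A", "r__fwd", "EX_B"})}

    def test_scale_guard(self, toys):
        with pytest.raises(CapacityError):
            gf.compute_efms(toys["branched"], guard=3)


class TestFrequencyAnalysis:
    def test_symmetric_isozymes_split_frequency(self, toys):
        ext = gf.transform_model(toys["efm_toy"])
        gene_freq, rxn_freq = gf.frequency_analysis(gf.compute_efms(ext), ext)
        assert gene_freq["gx"] == pytest.approx(1.0)
        assert gene_freq["gy"] == pytest.approx(0.5)
        assert gene_freq["gz"] == pytest.approx(0.5)
        assert rxn_freq["r3"] == pytest.approx(1.0)

    def test_absent_gene_zero(self, toys):
        m = toys["branched"]
        sc_ext = gf.transform_model(m)
        modes = gf.compute_efms(sc_ext)
        gene_freq, _ = gf.frequency_analysis(modes, sc_ext)
        assert set(gene_freq.index) == set(sc_ext.genes)
        assert (gene_freq >= 0).all() and (gene_freq <= 1).all()

    def test_empty_mode_set_rejected(self, toys):
        with pytest.raises(ModelError):
            gf.frequency_analysis([], toys["efm_toy"])


class TestCutSets:
    def test_unique_byproduct_cut(self, toys):
        """Anaerobically, deleting the lactate-like branch is the only
        size-1 deletion coupling ethanol yield to growth (checked against
        all subsets implicitly by the enumerator)."""
        m = toys["branched"]
        targets = [r.id for r in m.reactions.values() if r.gpr is not None]
        designs = gf.enumerate_cut_sets(m, anaerobic_scenario(), targets,
                                        max_size=1)
        assert [set(d.targets) for d in designs] == [{"r_lac"}]
        assert designs[0].feasible is True

    def test_empty_targetable_empty_result(self, toys):
        assert gf.enumerate_cut_sets(toys["branched"], anaerobic_scenario(),
                                     [], max_size=2) == []

    def test_gene_designs_direct_from_extended_model(self, toys):
        ext = gf.transform_model(toys["branched"])
        designs = gf.enumerate_cut_sets(ext, anaerobic_scenario(), ext.genes,
                                        max_size=1)
        assert [set(d.targets) for d in designs] == [{"gL"}]
        assert designs[0].kind == "gene"
        assert set(designs[0].effective_reaction_deletions) == {"r_lac"}

    def test_gene_designs_always_revalidate(self, toys):
        """Designs found on the extended model account for side effects by
        construction, so the independent audit agrees."""
        m = toys["branched"]
        ext = gf.transform_model(m)
        for d in gf.enumerate_cut_sets(ext, anaerobic_scenario(), ext.genes,
                                       max_size=2):
            audit = gf.validate_design(d, m, anaerobic_scenario())
            assert audit.feasible is True

    def test_supersets_are_pruned(self, toys):
        m = toys["branched"]
        targets = [r.id for r in m.reactions.values() if r.gpr is not None]
        designs = gf.enumerate_cut_sets(m, anaerobic_scenario(), targets,
                                        max_size=2)
        sets = [d.targets for d in designs]
        for a in sets:
            for b in sets:
                assert a == b or not a < b


class TestGeneDesignExpansion:
    def test_disjoint_complex_count_77(self):
        """Two OR-joined complexes with 11 and 7 disjoint subunits expand a
        single-reaction cut set to 77 gene designs."""
        m = gf.MetabolicModel("fhl")
        gpr = ("(" + " and ".join(f"a{i}" for i in range(11)) + ") or ("
               + " and ".join(f"b{i}" for i in range(7)) + ")")
        m.add_reaction(gf.Reaction("target", {"X": -1.0}, gpr=gf.parse_gpr(gpr)))
        design = gf.CutSetDesign(targets=frozenset({"target"}), kind="reaction")
        out = gf.expand_to_gene_designs(design, m)
        assert len(out) == 77
        assert all(d.size == 2 for d in out)

    def test_single_gene_target(self, toys):
        design = gf.CutSetDesign(targets=frozenset({"r_lac"}), kind="reaction")
        out = gf.expand_to_gene_designs(design, toys["branched"])
        assert [set(d.targets) for d in out] == [{"gL"}]

    def test_shared_subunit_fewer_than_naive_product(self):
        m = gf.MetabolicModel("shared")
        m.add_reaction(gf.Reaction("t1", {"X": -1.0},
                                   gpr=gf.parse_gpr("g1 and g2")))
        m.add_reaction(gf.Reaction("t2", {"Y": -1.0},
                                   gpr=gf.parse_gpr("g2 and g3")))
        design = gf.CutSetDesign(targets=frozenset({"t1", "t2"}), kind="reaction")
        out = gf.expand_to_gene_designs(design, m)
        # naive product is 2 x 2 = 4; {g2} absorbs the pairs containing it
        assert sorted(sorted(d.targets) for d in out) == [["g1", "g3"], ["g2"]]

    def test_gprless_target_is_an_error(self, toys):
        design = gf.CutSetDesign(targets=frozenset({"r_bio"}), kind="reaction")
        with pytest.raises(ModelError, match="no GPR"):
            gf.expand_to_gene_designs(design, toys["branched"])


class TestValidateDesign:
    def test_promiscuity_side_effect_invalidates_naive_design(self, toys):
        """The byproduct gene moonlights in the glycolysis complex: the
        naive gene translation of the valid reaction design kills growth
        and fails the audit."""
        m = toys["promiscuity_trap"]
        targets = [r.id for r in m.reactions.values() if r.gpr is not None]
        rdesigns = gf.enumerate_cut_sets(m, anaerobic_scenario(), targets,
                                         max_size=1)
        assert [set(d.targets) for d in rdesigns] == [{"r_lac"}]
        gene_designs = gf.expand_to_gene_designs(rdesigns[0], m)
        audit = gf.validate_design(gene_designs[0], m, anaerobic_scenario())
        assert audit.feasible is False
        assert audit.effective_reaction_deletions == frozenset({"r_lac", "r_gly"})

    def test_isozyme_deletion_misses_target(self, toys):
        m = toys["branched"]
        audit = gf.validate_design(
            gf.CutSetDesign(targets=frozenset({"gE1"}), kind="gene"),
            m, anaerobic_scenario())
        assert "r_eth" not in audit.effective_reaction_deletions
        assert audit.feasible is False

    def test_dedicated_single_gene_design_valid(self, toys):
        m = toys["branched"]
        audit = gf.validate_design(
            gf.CutSetDesign(targets=frozenset({"gL"}), kind="gene"),
            m, anaerobic_scenario())
        assert audit.feasible is True
        assert audit.effective_reaction_deletions == frozenset({"r_lac"})

    def test_effective_deletion_sets_not_more_numerous_than_designs(self, toys):
        m = toys["branched"]
        designs = [gf.validate_design(
            gf.CutSetDesign(targets=frozenset(t), kind="gene"), m,
            anaerobic_scenario())
            for t in (["gL"], ["gL", "gE1"], ["gL", "gE2"])]
        effective = {d.effective_reaction_deletions for d in designs}
        assert len(effective) <= len(designs)
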