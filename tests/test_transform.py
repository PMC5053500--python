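"""Extended-matrix construction, solution mapping, and soundness."""

import math

import numpy as np
import pytest

import gprflux as gf
from gprflux.model import ModelError
from gprflux.transform import check_gene_balance, extended_matrix

from conftest import check_original_feasibility


def three_reaction_toy():
    m = gf.MetabolicModel("toy3")
    m.add_reaction(gf.Reaction("r1", {"A": -1.0, "B": 1.0},
                               gpr=gf.parse_gpr("g1 and g2")))
    m.add_reaction(gf.Reaction("r2", {"B": -1.0, "C": 1.0},
                               gpr=gf.parse_gpr("g3 or g4")))
    m.add_reaction(gf.Reaction("r3", {"B": -1.0, "D": 1.0}, -1000.0, 1000.0))
    m.add_reaction(gf.Reaction("EX_A", {"A": 1.0}, 0, 10))
    m.add_reaction(gf.Reaction("EX_C", {"C": -1.0}, 0, 1000))
    m.add_reaction(gf.Reaction("EX_D", {"D": -1.0}, 0, 1000))
    m.objective = "EX_C"
    return m


class TestTransformStructure:
    def test_hand_counted_sizes(self):
        """r1 (complex), r2 (2 isozymes), r3 (reversible, no GPR) expand to
        r1 + r2a + r2b + r3f + r3b + 4 usage reactions and gain 4 gene
        species."""
        m = three_reaction_toy()
        for rid in ("EX_A", "EX_C", "EX_D"):
            del m.reactions[rid]
        m.objective = None
        ext = gf.transform_model(m)
        assert len(ext.base.reactions) == 9
        assert len(ext.base.metabolites) == 8  # A B C D + 4 gene species

    def test_sub_reaction_ids_deterministic(self):
        ext = gf.transform_model(three_reaction_toy())
        ids = {s.id for s in ext.split_map["r2"]}
        assert ids == {"r2__enz0", "r2__enz1"}
        ids3 = {s.id for s in ext.split_map["r3"]}
        assert ids3 == {"r3__fwd", "r3__bwd"}

    def test_all_sub_reactions_nonnegative_and_usage_unbounded(self):
        ext = gf.transform_model(three_reaction_toy())
        for rxn in ext.base.reactions.values():
            assert rxn.lower_bound >= 0.0
        for rid in ext.usage_reactions.values():
            rxn = ext.base.reactions[rid]
            assert rxn.lower_bound == 0.0 and math.isinf(rxn.upper_bound)

    def test_gene_species_produced_only_by_usage(self):
        ext = gf.transform_model(three_reaction_toy())
        for g, sid in ext.gene_species.items():
            producers = [r.id for r in ext.base.reactions.values()
                         if r.stoichiometry.get(sid, 0) > 0]
            assert producers == [ext.usage_reactions[g]]
            consumers = [r for r in ext.base.reactions.values()
                         if r.stoichiometry.get(sid, 0) < 0]
            for r in consumers:
                assert r.stoichiometry[sid] == -ext.copy_numbers[(g, r.id)]

    def test_block_structure(self):
        """Usage columns form the identity on gene rows, zero on metabolite
        rows."""
        ext = gf.transform_model(three_reaction_toy())
        S, rows, cols = extended_matrix(ext)
        k = len(ext.usage_reactions)
        n_met = len(rows) - k
        usage_block = S[:, -k:]
        assert np.allclose(usage_block[:n_met, :], 0.0)
        assert np.allclose(usage_block[n_met:, :], np.eye(k))

    def test_no_gpr_model_only_direction_splits(self):
        m = three_reaction_toy()
        for rxn in m.reactions.values():
            rxn.gpr = None
        ext = gf.transform_model(m)
        n_rev = sum(1 for r in m.reactions.values() if r.reversible)
        assert len(ext.base.reactions) == len(m.reactions) + n_rev
        assert not ext.usage_reactions

    def test_gpr_only_splitting_flag(self):
        ext = gf.transform_model(three_reaction_toy(), split_all_reversible=False)
        assert "r3" in {s.id for s in ext.split_map["r3"]}  # untouched
        assert "EX_D" in ext.base.reactions

    def test_copy_number_table_override(self):
        ext = gf.transform_model(three_reaction_toy(),
                                 copy_number_table={("g1", "r1"): 4})
        assert ext.copy_numbers[("g1", "r1")] == 4
        assert ext.base.reactions["r1"].stoichiometry["enz_g1"] == -4

    def test_mapping_table_sidecar(self):
        tab = gf.transform_model(three_reaction_toy()).mapping_table()
        assert set(tab.columns) == {"sub_reaction", "parent", "direction",
                                    "enzyme_index", "genes"}
        row = tab[tab.sub_reaction == "r1"].iloc[0]
        assert row.genes == "g1;g2"


class TestOptimumEquality:
    def test_extended_fba_equals_original_on_toys(self, toys):
        for name, m in toys.items():
            ext = gf.transform_model(m)
            a = gf.fba(m)
            b = gf.fba(ext)
            assert a.status == b.status == "optimal"
            assert b.objective_value == pytest.approx(a.objective_value, abs=1e-6), name

    def test_extended_fba_equals_original_random(self):
        for seed in range(25):
            m = gf.random_model(n_reactions=9, seed=seed)
            ext = gf.transform_model(m)
            a = gf.fba(m)
            b = gf.fba(ext)
            assert b.objective_value == pytest.approx(a.objective_value, abs=1e-6)

    def test_collapsed_solution_feasible_in_original(self, toys):
        for m in toys.values():
            ext = gf.transform_model(m)
            res = gf.pfba(ext, level="gene")
            col = gf.collapse_solution(ext, res.solution)
            check_original_feasibility(m, col.fluxes)

    def test_gene_species_balance_in_solutions(self, toys):
        for m in toys.values():
            ext = gf.transform_model(m)
            for res in (gf.fba(ext), gf.pfba(ext, level="gene")):
                assert check_gene_balance(ext, res.solution) <= 1e-6


class TestCollapse:
    def test_isozyme_sum_and_net_flux(self):
        ext = gf.transform_model(three_reaction_toy())
        sol = gf.GeneLevelSolution(
            sub_fluxes={"r2__enz0": 0.3, "r2__enz1": 0.7,
                        "r3__fwd": 2.0, "r3__bwd": 0.5},
            usage={}, objective_value=1.0)
        col = gf.collapse_solution(ext, sol)
        assert col.fluxes["r2"] == pytest.approx(1.0)
        assert col.fluxes["r3"] == pytest.approx(1.5)

    def test_unknown_sub_reaction_rejected(self):
        ext = gf.transform_model(three_reaction_toy())
        sol = gf.GeneLevelSolution(sub_fluxes={"nope": 1.0}, usage={})
        with pytest.raises(KeyError):
            gf.collapse_solution(ext, sol)


class TestGeneConstraints:
    def test_isozyme_redundancy(self):
        ext = gf.transform_model(three_reaction_toy())
        ko = gf.apply_gene_constraints(ext, {"g3": (0.0, 0.0)})
        res = gf.fba(ko)
        assert res.objective_value == pytest.approx(10.0)  # g4 isozyme carries

    def test_complex_subunit_knockout_blocks_enzyme(self):
        ext = gf.transform_model(three_reaction_toy())
        ko = gf.apply_gene_constraints(ext, {"g1": (0.0, 0.0)})
        res = gf.fba(ko)
        assert res.objective_value == pytest.approx(0.0)  # r1 is sole route

    def test_forced_usage_bounds(self):
        """u_g fixed to [2,2] forces the catalyzed flux total to 2."""
        ext = gf.transform_model(three_reaction_toy())
        forced = gf.apply_gene_constraints(ext, {"g3": (2.0, 2.0)})
        rng = gf.fva(forced, variables=["r2__enz0"])
        assert rng["r2__enz0"] == pytest.approx((2.0, 2.0), abs=1e-6)

    def test_unknown_gene_and_bad_bounds(self):
        ext = gf.transform_model(three_reaction_toy())
        with pytest.raises(ModelError):
            gf.apply_gene_constraints(ext, {"nope": (0.0, 0.0)})
        with pytest.raises(ModelError):
            gf.apply_gene_constraints(ext, {"g1": (2.0, 1.0)})


class TestRemoveBlocked:
    def test_dead_end_branch_removed(self):
        m = three_reaction_toy()
        m.add_reaction(gf.Reaction("r_dead", {"B": -1.0, "X": 1.0}))
        simplified = gf.remove_blocked(m)
        assert "r_dead" not in simplified.reactions
        assert "X" not in simplified.metabolites
        assert gf.fba(simplified).objective_value == pytest.approx(
            gf.fba(m).objective_value)

    def test_fully_coupled_pathway_unchanged(self, toys):
        m = toys["efm_toy"]
        simplified = gf.remove_blocked(m)
        assert set(simplified.reactions) == set(m.reactions)

    def test_blocked_objective_raises(self):
        m = three_reaction_toy()
        m.reactions["EX_A"].upper_bound = 0.0  # no carbon in
        with pytest.raises(ModelError):
            gf.remove_blocked(m)
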