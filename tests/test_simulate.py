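"""FBA/pFBA, the MOMA family, modulation, FVA and essentiality."""

import numpy as np
import pytest

import gprflux as gf
from gprflux.model import ModelError

from conftest import essentiality_by_knockout


def linear_chain(fix_uptake=None):
    """uptake -> A -> P -> growth, single gene per step."""
    m = gf.MetabolicModel("chain")
    ub = 10.0
    lb = fix_uptake if fix_uptake is not None else 0.0
    if fix_uptake is not None:
        ub = fix_uptake
    m.add_reaction(gf.Reaction("EX_A", {"A": 1.0}, lb, ub))
    m.add_reaction(gf.Reaction("r1", {"A": -1.0, "P": 2.0},
                               gpr=gf.parse_gpr("gc")))
    m.add_reaction(gf.Reaction("r_bio", {"P": -1.0}))
    m.objective = "r_bio"
    return m


class TestFBA:
    def test_closed_form_yield(self):
        # uptake 10, 2 P per A: growth = 20
        assert gf.fba(linear_chain()).objective_value == pytest.approx(20.0)

    def test_zero_carbon_zero_growth(self):
        m = linear_chain()
        m.reactions["EX_A"].upper_bound = 0.0
        assert gf.fba(m).objective_value == pytest.approx(0.0)

    def test_minimize_sense(self):
        res = gf.fba(linear_chain(), objective_sense="min")
        assert res.objective_value == pytest.approx(0.0)

    def test_infeasible_reported_not_silent(self):
        m = linear_chain(fix_uptake=5.0)
        m.reactions["r1"].upper_bound = 0.0  # uptake forced but unusable
        res = gf.fba(m)
        assert res.status == "infeasible"
        assert res.solution is None

    def test_diagnostics_exposed(self):
        res = gf.fba(linear_chain(), diagnostics=True)
        assert res.diagnostics is not None
        assert res.diagnostics["shadow_prices"] is not None


class TestPFBA:
    def test_growth_fixed_at_fba_optimum(self, toys):
        for m in toys.values():
            f = gf.fba(m).objective_value
            for level, target in (("reaction", m),
                                  ("gene", gf.transform_model(m))):
                res = gf.pfba(target, level=level)
                assert res.objective_value == pytest.approx(f, abs=1e-6)

    def test_unique_optimum_equals_fba(self):
        m = linear_chain()
        a = gf.fba(m).solution.fluxes
        b = gf.pfba(m).solution.fluxes
        for rid in a:
            assert b[rid] == pytest.approx(a[rid], abs=1e-6)

    def test_gene_pfba_prefers_cheap_enzyme(self, toys):
        """With a 5-subunit complex vs a monomeric isozyme, minimizing
        enzyme usage routes all flux through the monomer (cost 1 vs 5 gene
        units per flux unit)."""
        ext = gf.transform_model(toys["two_isozyme"])
        res = gf.pfba(ext, level="gene")
        assert res.solution.usage["m1"] == pytest.approx(10.0, abs=1e-6)
        for g in ("c1", "c2", "c3", "c4", "c5"):
            assert res.solution.usage[g] == pytest.approx(0.0, abs=1e-6)
        # total usage is the hand value 10 (monomer) not 50 (complex)
        assert sum(res.solution.usage.values()) == pytest.approx(10.0, abs=1e-5)

    def test_reaction_pfba_vs_gene_pfba_can_disagree(self, toys):
        """Flux totals equal here, but the usage-based objective value is
        what distinguishes the two stages."""
        ext = gf.transform_model(toys["two_isozyme"])
        r = gf.pfba(ext, level="reaction")
        g = gf.pfba(ext, level="gene")
        assert r.objective_value == pytest.approx(g.objective_value)


class TestMOMA:
    def test_empty_deletion_returns_reference(self, toys):
        ext = gf.transform_model(toys["two_isozyme"])
        for norm in ("quadratic", "linear"):
            res = gf.moma(ext, level="gene", norm=norm)
            assert res.metadata["deviation"] == pytest.approx(0.0, abs=1e-5)

    def test_hand_solved_isozyme_rerouting(self, toys):
        """Fixed uptake 10; wild type uses the monomer (u_m1 = 10).  After
        deleting m1 all flux must run through the 5-subunit complex:
        quadratic deviation 5*10^2 + 10^2 = 600, linear deviation 60."""
        m = toys["two_isozyme"]
        m.reactions["EX_S"].lower_bound = 10.0  # chemostat-style fixed uptake
        ext = gf.transform_model(m)
        ref = gf.pfba(ext, level="gene")
        q = gf.moma(ext, deleted_genes=["m1"], level="gene",
                    norm="quadratic", reference=ref)
        assert q.status == "optimal"
        assert q.metadata["deviation"] == pytest.approx(600.0, rel=1e-4)
        for g in ("c1", "c2", "c3", "c4", "c5"):
            assert q.solution.usage[g] == pytest.approx(10.0, abs=1e-4)
        lin = gf.moma(ext, deleted_genes=["m1"], level="gene",
                      norm="linear", reference=ref)
        assert lin.metadata["deviation"] == pytest.approx(60.0, abs=1e-5)
        # reaction-level net flux is unchanged by swapping isozymes
        col = gf.collapse_solution(ext, q.solution)
        assert col.fluxes["r_cat"] == pytest.approx(10.0, abs=1e-4)

    def test_essential_deletion_is_infeasible_signal(self):
        m = linear_chain(fix_uptake=5.0)
        ext = gf.transform_model(m)
        res = gf.moma(ext, deleted_genes=["gc"], level="gene", norm="linear")
        assert res.status == "infeasible"

    def test_deviation_monotone_in_nested_deletions(self, toys):
        m = toys["branched"]
        m.reactions["r_up"].lower_bound = 10.0
        ext = gf.transform_model(m)
        ref = gf.pfba(ext, level="gene")
        devs = []
        for dels in ([], ["gE1"], ["gE1", "gR"]):
            res = gf.moma(ext, deleted_genes=dels, level="gene",
                          norm="linear", reference=ref)
            devs.append(res.metadata["deviation"])
        assert devs[0] <= devs[1] + 1e-6 <= devs[2] + 2e-6

    def test_reaction_level_moma_on_plain_model(self):
        m = linear_chain(fix_uptake=5.0)
        ref = gf.pfba(m)
        res = gf.moma(m, level="reaction", norm="linear", reference=ref)
        assert res.metadata["deviation"] == pytest.approx(0.0, abs=1e-6)


class TestModulation:
    def test_lambda_one_is_wild_type(self, toys):
        ext = gf.transform_model(toys["lpd_like"])
        res = gf.simulate_modulation(ext, "L", 1.0)
        assert res.objective_value == pytest.approx(
            gf.fba(ext).objective_value, abs=1e-6)

    def test_halving_sole_catalyst_halves_growth(self):
        ext = gf.transform_model(linear_chain())
        res = gf.simulate_modulation(ext, "gc", 0.5)
        assert res.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_staged_nonlinear_response_of_shared_subunit(self, toys):
        """Down-regulating the shared subunit L first displaces flux from
        the reaction with an isozyme backup (r1) and only below the
        breakpoint reduces growth: a non-linear, reaction-specific effect
        that reaction-level bounds cannot express."""
        ext = gf.transform_model(toys["lpd_like"])
        growth = {lam: gf.simulate_modulation(ext, "L", lam).objective_value
                  for lam in (1.0, 0.7, 0.5, 0.3)}
        assert growth[0.7] == pytest.approx(growth[1.0], abs=1e-6)
        assert growth[0.5] == pytest.approx(growth[1.0], abs=1e-6)
        assert growth[0.3] == pytest.approx(3.0, abs=1e-6)

    def test_growth_non_increasing_away_from_optimum(self, toys):
        ext = gf.transform_model(toys["lpd_like"])
        lams = [0.2, 0.4, 0.6, 0.8, 1.0]
        vals = [gf.simulate_modulation(ext, "L", lam).objective_value
                for lam in lams]
        assert all(vals[i] <= vals[i + 1] + 1e-8 for i in range(len(vals) - 1))

    def test_invalid_lambda_rejected(self, toys):
        ext = gf.transform_model(toys["lpd_like"])
        with pytest.raises(ModelError):
            gf.simulate_modulation(ext, "L", 0.0)


class TestFVA:
    def test_essential_single_path_pinned(self):
        m = linear_chain(fix_uptake=5.0)
        rng = gf.fva(m, variables=["r1"])
        assert rng["r1"] == pytest.approx((5.0, 5.0), abs=1e-6)

    def test_redundant_isozyme_min_zero(self, toys):
        ext = gf.transform_model(toys["two_isozyme"])
        rng = gf.fva(ext, variables=["r_cat__enz0", "r_cat__enz1"],
                     growth_fraction=1.0)
        for key, (lo, hi) in rng.items():
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_gene_variables_resolve_to_usage(self, toys):
        ext = gf.transform_model(toys["efm_toy"])
        rng = gf.fva(ext, variables=["gx"], growth_fraction=1.0)
        assert rng["gx"] == pytest.approx((10.0, 10.0), abs=1e-6)


class TestEssentiality:
    def test_fva_essentiality_equals_knockout(self, toys):
        for name, m in toys.items():
            ext = gf.transform_model(m)
            table = gf.gene_essentiality(ext)
            by_fva = set(table.index[table.essential])
            by_ko = essentiality_by_knockout(ext)
            assert by_fva == by_ko, name

    def test_blocked_gene_detected(self):
        m = linear_chain()
        m.add_reaction(gf.Reaction("r_dead", {"A": -1.0, "X": 1.0},
                                   gpr=gf.parse_gpr("gdead")))
        ext = gf.transform_model(m)
        table = gf.gene_essentiality(ext)
        assert bool(table.loc["gdead", "blocked"])
        assert not bool(table.loc["gc", "blocked"])
        assert bool(table.loc["gc", "essential"])

    def test_infeasible_baseline_raises_not_all_essential(self):
        m = linear_chain(fix_uptake=5.0)
        m.reactions["r1"].upper_bound = 0.0
        ext = gf.transform_model(m)
        with pytest.raises(ModelError):
            gf.gene_essentiality(ext)
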