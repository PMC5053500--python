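"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive truth tables, subset
enumeration, nullspace rank tests) and independent of the implementation
paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import gprflux as gf


@pytest.fixture
def toys():
    return gf.toy_models()


# ---------------------------------------------------------------------------
# random GPR expressions
# ---------------------------------------------------------------------------


def random_gpr_text(rng, max_genes=8, depth=0):
    """A random AND/OR/parenthesis expression over a small gene pool."""
    n_genes = int(rng.integers(1, max_genes + 1))
    pool = [f"g{i}" for i in range(n_genes)]

    def node(d):
        if d >= 3 or rng.random() < 0.4:
            return rng.choice(pool)
        op = " and " if rng.random() < 0.5 else " or "
        k = int(rng.integers(2, 4))
        children = [node(d + 1) for _ in range(k)]
        return "(" + op.join(children) + ")"

    return node(depth), pool


def truth_table_equal(assoc, pool):
    """Exhaustively compare original-expression and DNF evaluation over all
    gene on/off assignments."""
    genes = sorted(set(pool) | set(assoc.genes))
    for states in itertools.product([False, True], repeat=len(genes)):
        active = {g for g, s in zip(genes, states) if s}
        deleted = set(genes) - active
        if assoc.evaluate_expression(active) != assoc.evaluate(deleted):
            return False
    return True


def brute_force_hitting_sets(families):
    """All inclusion-minimal hitting sets by subset enumeration."""
    universe = sorted(set().union(*families))
    hitting = []
    for k in range(0, len(universe) + 1):
        for combo in itertools.combinations(universe, k):
            s = set(combo)
            if all(s & set(f) for f in families):
                if not any(h <= s for h in hitting):
                    hitting.append(s)
    return sorted(hitting, key=lambda s: sorted(s))


# ---------------------------------------------------------------------------
# brute-force EFM support oracle
# ---------------------------------------------------------------------------


def brute_force_efm_supports(S, ids, tol=1e-9):
    """Supports of all elementary modes of {v >= 0 : S v = 0} by testing
    every reaction subset: a subset is elementary iff the kernel of its
    column restriction is one-dimensional with a strictly signed generator,
    and no proper subset qualifies."""
    import scipy.linalg

    n = S.shape[1]
    candidates = []
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            sub = S[:, combo]
            null = scipy.linalg.null_space(sub)
            if null.shape[1] != 1:
                continue
            v = null[:, 0]
            if np.all(v > tol) or np.all(v < -tol):
                candidates.append(frozenset(ids[j] for j in combo))
    minimal = {c for c in candidates
               if not any(o < c for o in candidates)}
    return minimal


def essentiality_by_knockout(ext, growth_fraction=0.1, tol=1e-6):
    """Essential genes by the classical two-stage route: evaluate the GPRs,
    knock out, re-run FBA, compare to the required growth."""
    wt = gf.fba(ext)
    assert wt.optimal
    required = growth_fraction * wt.objective_value
    essential = set()
    for g in ext.genes:
        ko = gf.apply_gene_constraints(ext, {g: (0.0, 0.0)})
        res = gf.fba(ko)
        if not res.optimal or res.objective_value < required - tol:
            essential.add(g)
    return essential


def check_original_feasibility(model, fluxes, tol=1e-6):
    """Verify a reaction-level flux dict against S v = 0 and the bounds."""
    S, mets, rxns = model.stoichiometric_matrix()
    v = np.array([fluxes[r] for r in rxns])
    internal = [i for i, m in enumerate(mets)
                if not model.metabolites[m].is_external]
    assert np.max(np.abs(S[internal] @ v)) <= tol if internal else True
    for r in rxns:
        rxn = model.reactions[r]
        assert rxn.lower_bound - tol <= fluxes[r] <= rxn.upper_bound + tol, r
    return True
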