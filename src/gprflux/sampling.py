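"""Uniform-style flux sampling of original and extended models.

A plain hit-and-run walk over the flux polytope, run in the nullspace of the
stoichiometric matrix so every sample satisfies the steady-state balances by
construction.  Scenario presets reproduce the two study conditions used for
gene-level distribution comparison: a wild-type phenotype constrained to at
least 90% of the maximal biomass yield, and a producer phenotype with at
least 10% of the biomass yield and at least 90% of the maximal product
formation attainable at that biomass level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import ModelError
from .simulate import LinearView, _maximize_growth, _stack_eq, _ub_rows
from .solver import solve_lp

__all__ = [
    "SampleSet",
    "sample_fluxes",
    "wildtype_scenario",
    "producer_scenario",
    "compare_distributions",
]

BALANCE_TOL = 1e-6


@dataclass
class SampleSet:
    """Samples (rows) over the model's flux/usage variables (columns),
    with the scenario label and the seed that produced them."""

    samples: "object"  # pandas DataFrame
    scenario: str = ""
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.samples)

    def values(self, variable) -> np.ndarray:
        return self.samples[variable].to_numpy()


def wildtype_scenario(m, fraction: float = 0.9) -> list:
    """Inequality rows pinning growth to >= ``fraction`` of its maximum."""
    view = LinearView(m)
    res = _maximize_growth(view)
    if not res.optimal:
        raise ModelError(f"scenario baseline is {res.status}")
    vmax = -res.fun
    return [({j: -c for j, c in view.growth_expr.items()}, -fraction * vmax)]


def producer_scenario(m, product: str, growth_fraction: float = 0.1,
                      product_fraction: float = 0.9) -> list:
    """Producer phenotype: growth >= ``growth_fraction`` of max, product
    >= ``product_fraction`` of the maximal production at that growth."""
    view = LinearView(m)
    res = _maximize_growth(view)
    if not res.optimal:
        raise ModelError(f"scenario baseline is {res.status}")
    mu_min = growth_fraction * (-res.fun)
    growth_row = ({j: -c for j, c in view.growth_expr.items()}, -mu_min)
    prod_expr = view.expression_for(product)
    n = len(view.ids)
    c = np.zeros(n)
    for j, coef in prod_expr.items():
        c[j] = -coef
    A_eq, b_eq = _stack_eq(view, [])
    A_ub, b_ub = _ub_rows(n, [growth_row])
    res2 = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=view.bounds, A_ub=A_ub, b_ub=b_ub)
    if not res2.optimal:
        raise ModelError("cannot maximize product in producer scenario")
    pmax = -res2.fun
    product_row = ({j: -coef for j, coef in prod_expr.items()},
                   -product_fraction * pmax)
    return [growth_row, product_row]


def sample_fluxes(m, scenario_constraints=(), n_samples: int = 10_000,
                  thinning: int = 100, seed: int | None = None,
                  scenario: str = "") -> SampleSet:
    """Hit-and-run sampling of the constrained flux polytope.

    ``scenario_constraints`` is a list of ``(expression, rhs)`` inequality
    rows (``expression . v <= rhs``) as produced by the scenario presets.
    The walk starts from a Chebyshev-style interior point (maximum slack LP)
    and keeps every ``thinning``-th step.  The polytope must be bounded:
    an unbounded direction raises an error demanding finite bounds.
    Fixing ``seed`` makes the sample set bit-identical across runs.
    """
    import pandas as pd

    view = LinearView(m)
    n = len(view.ids)
    lb = np.array([b[0] for b in view.bounds], dtype=float)
    ub = np.array([b[1] for b in view.bounds], dtype=float)
    rows = []
    rhs = []
    for expr, value in scenario_constraints:
        row = np.zeros(n)
        for j, c in expr.items():
            row[j] = c
        rows.append(row)
        rhs.append(value)
    G = np.vstack(rows) if rows else np.zeros((0, n))
    h = np.array(rhs)

    A = view.A.toarray()
    N = scipy.linalg.null_space(A) if A.size else np.eye(n)
    # unbounded directions (e.g. a direction moving only infinity-bounded
    # usage variables) surface as infinite chords during the walk and raise

    # interior start: maximize the smallest slack (Chebyshev-style)
    # variables (y, t): x = x0 + N y
    feas = solve_lp(np.zeros(n), A_eq=view.A, b_eq=np.zeros(A.shape[0]),
                    bounds=view.bounds, A_ub=G if len(G) else None,
                    b_ub=h if len(G) else None)
    if not feas.optimal:
        raise ModelError(f"sampling region is {feas.status}")
    x0 = feas.x
    k = N.shape[1] if N.size else 0
    if k == 0:
        data = np.tile(x0, (n_samples, 1))
        return SampleSet(pd.DataFrame(data, columns=view.ids),
                         scenario=scenario, seed=seed)

    c = np.zeros(k + 1)
    c[-1] = -1.0  # maximize t
    A_rows = []
    b_rows = []
    for i in range(n):
        if np.all(np.abs(N[i]) < 1e-12):
            continue
        if np.isfinite(ub[i]):
            A_rows.append(np.concatenate([N[i], [1.0]]))   # x0+Ny + t <= ub
            b_rows.append(ub[i] - x0[i])
        if np.isfinite(lb[i]):
            A_rows.append(np.concatenate([-N[i], [1.0]]))  # -(x0+Ny) + t <= -lb
            b_rows.append(x0[i] - lb[i])
    for gi, hv in zip(G, h):
        gN = gi @ N
        A_rows.append(np.concatenate([gN, [np.linalg.norm(gN) or 1.0]]))
        b_rows.append(hv - gi @ x0)
    start = solve_lp(c, A_ub=np.vstack(A_rows), b_ub=np.array(b_rows),
                     bounds=[(None, None)] * k + [(0.0, 1e6)])
    if not start.optimal:
        raise ModelError("cannot find an interior starting point")
    x = x0 + N @ start.x[:k]
    x = np.clip(x, lb, ub)

    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, n))
    eps = 1e-12
    collected = 0
    step = 0
    while collected < n_samples:
        g = rng.standard_normal(k)
        d = N @ g
        nrm = np.linalg.norm(d)
        if nrm < eps:
            continue
        d /= nrm
        alpha_lo, alpha_hi = -np.inf, np.inf
        for i in np.flatnonzero(np.abs(d) > eps):
            a1 = (lb[i] - x[i]) / d[i]
            a2 = (ub[i] - x[i]) / d[i]
            lo, hi = (a1, a2) if a1 <= a2 else (a2, a1)
            alpha_lo = max(alpha_lo, lo)
            alpha_hi = min(alpha_hi, hi)
        for gi, hv in zip(G, h):
            gd = gi @ d
            if abs(gd) > eps:
                a = (hv - gi @ x) / gd
                if gd > 0:
                    alpha_hi = min(alpha_hi, a)
                else:
                    alpha_lo = max(alpha_lo, a)
        if not np.isfinite(alpha_lo) or not np.isfinite(alpha_hi):
            raise ModelError("unbounded chord encountered; set finite bounds")
        if alpha_hi <= alpha_lo:
            continue
        x = x + rng.uniform(alpha_lo, alpha_hi) * d
        x = np.clip(x, lb, ub)
        step += 1
        if step % thinning == 0:
            out[collected] = x
            collected += 1
    return SampleSet(pd.DataFrame(out, columns=view.ids),
                     scenario=scenario, seed=seed)


def compare_distributions(a: SampleSet, b: SampleSet, variable) -> float:
    """Histogram-intersection overlap of two sampled flux distributions.

    Bins are shared (Freedman-Diaconis on the pooled values); the score is
    the intersection mass in [0, 1].  A score of 0 flags a variable whose
    flux must necessarily change between the two phenotypes, making the
    corresponding gene a target for expression modulation.
    """
    if a.n == 0 or b.n == 0:
        raise ModelError("empty sample set")
    va = a.values(variable)
    vb = b.values(variable)
    pooled = np.concatenate([va, vb])
    lo, hi = pooled.min(), pooled.max()
    if hi - lo < 1e-12:  # both essentially constant and equal
        return 1.0
    edges = np.histogram_bin_edges(pooled, bins="fd")
    if len(edges) < 3:
        edges = np.linspace(lo, hi, 11)
    pa, _ = np.histogram(va, bins=edges)
    pb, _ = np.histogram(vb, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())
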