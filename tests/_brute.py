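"""Independent brute-force oracles for the two ILP subproblems.

These enumerate the feasible set directly (permutations, copy-number grids,
simplex grids) and never touch the MILP builder, so agreement with the solver
is a genuine two-route check.
"""

from __future__ import annotations

import itertools

import numpy as np


def u_step_grid(F: np.ndarray, C: np.ndarray, step: float = 0.01) -> float:
    """Minimum of |F - UC|_1 over row-stochastic U by simplex grid search.

    Rows are independent, so each sample row is minimized separately over the
    lattice of simplex points with coordinates in multiples of ``step``.
    """
    F = np.asarray(F, float)
    C = np.asarray(C, float)
    n = C.shape[0]
    ticks = int(round(1.0 / step))
    best_total = 0.0
    grid = []
    for combo in itertools.combinations_with_replacement(range(ticks + 1), n - 1):
        # stars-and-bars: cumulative cut points -> composition of `ticks`
        cuts = (0,) + combo + (ticks,)
        parts = np.diff(cuts)
        grid.append(parts / ticks)
    grid = np.asarray(grid)
    mix = grid @ C
    for i in range(F.shape[0]):
        best_total += float(np.abs(mix - F[i]).sum(axis=1).min())
    return best_total


def c_step_enumerate(F, U, C_rna, Q, pi, pi_valid, lambda1, lambda2,
                     c_max: int = 2) -> float:
    """Exhaustive C-step optimum for n = 3 (the unique chain tree 2->1->0).

    Enumerates the RNA-clone permutation M, per-segment allele copy-number
    columns, and per-mutation allele choice and copy numbers.  For a chain of
    two mutable clones every presence pattern is Dollo-feasible (gain on
    either edge, losses below), so the only mutation-column constraints are
    the allele-gated segment bounds.  Costs are additive over segments given
    M, which keeps the enumeration tractable.
    """
    F = np.asarray(F, float)
    U = np.asarray(U, float)
    C_rna = np.asarray(C_rna, float)
    m = F.shape[0]
    n = 3
    r = C_rna.shape[1] // 2
    n_mut = Q.shape[0]
    l = pi.shape[1]
    seg_of = np.argmax(Q, axis=1)
    root = n - 1

    vals = range(c_max + 1)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        MC = C_rna[list(perm)]          # row i of M @ C_rna
        total = 0.0
        for s in range(r):
            muts = [b for b in range(n_mut) if seg_of[b] == s]
            best_seg = np.inf
            for a1_0, a1_1, a2_0, a2_1 in itertools.product(vals, repeat=4):
                col1 = np.array([a1_0, a1_1, 1.0])   # allele-1 column, root=1
                col2 = np.array([a2_0, a2_1, 1.0])
                cost = 0.0
                for col, cidx in ((col1, n_mut + s), (col2, n_mut + r + s)):
                    cost += np.abs(F[:, cidx] - U @ col).sum()          # data fit
                    cost += np.abs(col - MC[:, cidx - n_mut]).sum()     # RNA fit
                    # chain tree cost: edges (2,1) and (1,0)
                    cost += lambda1 * (abs(col[2] - col[1]) + abs(col[1] - col[0]))
                for b in muts:
                    best_mut = np.inf
                    for D_b in (0, 1):
                        gate = col1 if D_b == 1 else col2
                        for c0 in range(int(gate[0]) + 1):
                            for c1 in range(int(gate[1]) + 1):
                                mcol = np.array([c0, c1, 0.0])
                                mc = np.abs(F[:, b] - U @ mcol).sum()
                                if b < l:
                                    for i in range(m):
                                        if pi_valid[i, b]:
                                            est_s = U[i] @ (col1 + col2)
                                            mc += lambda2 * abs(
                                                U[i] @ mcol - pi[i, b] * est_s)
                                best_mut = min(best_mut, mc)
                    cost += best_mut
                best_seg = min(best_seg, cost)
            total += best_seg
            if total >= best:
                break
        best = min(best, total)
    return float(best)


def match_cost_exhaustive(C_true, C_est) -> float:
    """Minimum total L1 genotype distance over all clone permutations."""
    n = C_true.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        best = min(best, float(np.abs(C_true - C_est[list(perm)]).sum()))
    return best
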