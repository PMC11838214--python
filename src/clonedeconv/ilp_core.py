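"""The two coordinate-descent subproblems as (integer) linear programs.

U-step: with clone genotypes C fixed, the mixture fractions U minimizing
the L1 deconvolution residual |F - UC| subject to each sample row lying on
the probability simplex.  This is a plain LP.

C-step: with U fixed, a MILP over the integer genotype matrix C, the
RNA-clone assignment permutation M, the rooted binary tree E with ancestry
closure A, the Dollo gain placement W, and the allele assignment D, minimizing

    |F - UC| + |C' - M C_rna| + lambda1 * R + lambda2 * S

where C' is the segment block of C, R is the L1 copy-number distance summed
over tree edges, and S penalizes disagreement between observed and implied
breakpoint/segment mixture copy-number ratios.

All L1 terms and the edge-activated distances are linearized with auxiliary
variables and big-M constants equal to c_max (valid because every copy
number is bounded by c_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._milp import InfeasibleError, LinearModel, MilpResult, SolverBackend
from .data_model import (BulkProfile, DescentConfig, PiRatios, ProblemDims,
                         Regularizers, RnaCloneProfile, Solution)

__all__ = [
    "solve_u_step", "build_c_step", "solve_c_step", "CStepModel",
    "SolverBackend", "InfeasibleError", "ancestry_closure", "objective_terms",
]


def ancestry_closure(E: np.ndarray) -> np.ndarray:
    """Strict-ancestry (reachability) closure of a tree adjacency matrix."""
    n = E.shape[0]
    A = (np.asarray(E) != 0).astype(np.int8)
    reach = A.astype(bool)
    for _ in range(n):
        newly = reach @ reach | reach
        if (newly == reach).all():
            break
        reach = newly
    return reach.astype(np.int8)


# ---------------------------------------------------------------------------
# U-step
# ---------------------------------------------------------------------------

def solve_u_step(F: np.ndarray, C: np.ndarray, *, ratio=None,
                 backend: Optional[SolverBackend] = None):
    """Minimize ``|F - UC|_1`` over row-stochastic nonnegative U (an LP).

    ``ratio``, if given, is ``(pi, valid, seg1_cols, seg2_cols, lambda2)``:
    the breakpoint-consistency cost ``lambda2 * S`` is linear in U when C is
    fixed, and including it keeps the full objective a true coordinate
    descent.  The returned ``obj1`` is always the bare residual ``|F - UC|``.

    Returns ``(U, obj1)``.
    """
    F = np.asarray(F, dtype=float)
    C = np.asarray(C, dtype=float)
    m, K = F.shape
    n = C.shape[0]
    model = LinearModel()
    U_idx = model.add_vars((m, n), lb=0.0, ub=1.0)
    Fd_idx = model.add_vars((m, K), lb=0.0)
    for i in range(m):
        model.add_constraint(U_idx[i], np.ones(n), lb=1.0, ub=1.0)
    for i in range(m):
        for k in range(K):
            cols = np.concatenate(([Fd_idx[i, k]], U_idx[i]))
            # Fd >= F - U.C  and  Fd >= U.C - F
            model.add_constraint(cols, np.concatenate(([1.0], C[:, k])), lb=F[i, k])
            model.add_constraint(cols, np.concatenate(([1.0], -C[:, k])), lb=-F[i, k])
    model.add_objective(Fd_idx, 1.0)

    if ratio is not None:
        pi, valid, seg1, seg2, lam2 = ratio
        l = pi.shape[1]
        for i in range(m):
            for b in range(l):
                if not valid[i, b]:
                    continue
                coef = C[:, b] - pi[i, b] * (C[:, seg1[b]] + C[:, seg2[b]])
                s_idx = model.add_vars((), lb=0.0)
                cols = np.concatenate(([s_idx], U_idx[i]))
                model.add_constraint(cols, np.concatenate(([1.0], coef)), lb=0.0)
                model.add_constraint(cols, np.concatenate(([1.0], -coef)), lb=0.0)
                model.add_objective(np.asarray([s_idx]), lam2)

    res = model.solve(backend or SolverBackend())
    if res.x is None:
        raise InfeasibleError("U-step LP returned no solution: " + res.message)
    U = res.x[U_idx]
    # renormalize away solver tolerance drift
    U = np.clip(U, 0.0, None)
    U /= U.sum(axis=1, keepdims=True)
    obj1 = float(np.abs(F - U @ C).sum())
    return U, obj1


# ---------------------------------------------------------------------------
# C-step
# ---------------------------------------------------------------------------

@dataclass
class CStepModel:
    """Assembled C-step MILP plus the variable-index bookkeeping."""

    model: LinearModel
    dims: ProblemDims
    reg: Regularizers
    cfg: DescentConfig
    U: np.ndarray
    C_rna: np.ndarray
    F: np.ndarray
    Q: np.ndarray
    pi: PiRatios
    idx: dict = field(default_factory=dict)
    edges_allowed: list = field(default_factory=list)
    var_counts: dict = field(default_factory=dict)

    def pack(self, C, M, E, W, D) -> np.ndarray:
        """Assemble a full variable vector from a candidate solution.

        Ancestry, presence indicators and every L1 auxiliary are derived from
        the candidate, so ``model.max_violation(pack(...))`` tests whether the
        candidate satisfies the constraint set (used to verify that planted
        simulator truths are feasible).
        """
        d = self.dims
        x = np.zeros(self.model.n_vars)
        A = ancestry_closure(E)
        y = (np.asarray(C)[:, :d.n_mut] >= 1).astype(int)
        x[self.idx["C"]] = C
        x[self.idx["M"]] = M
        x[self.idx["E"]] = E
        x[self.idx["A"]] = A
        x[self.idx["W"]] = W
        x[self.idx["D"]] = D
        x[self.idx["y"]] = y
        Cseg = np.asarray(C)[:, d.n_mut:]
        x[self.idx["Cd"]] = np.abs(Cseg - np.asarray(M) @ self.C_rna)
        x[self.idx["Fd"]] = np.abs(self.F - self.U @ np.asarray(C))
        rho = np.zeros_like(self.idx["rho"], dtype=float)
        for e, (i, j) in enumerate(self.edges_allowed):
            if E[i, j]:
                rho[e] = np.abs(Cseg[i] - Cseg[j])
        x[self.idx["rho"]] = rho
        if len(self.idx["sigma"]):
            seg1, seg2 = self.idx["seg_cols"]
            for t, (i, b) in enumerate(self.idx["sigma_entries"]):
                est_b = float(self.U[i] @ np.asarray(C)[:, b])
                est_s = float(self.U[i] @ (np.asarray(C)[:, seg1[b]] + np.asarray(C)[:, seg2[b]]))
                x[self.idx["sigma"][t]] = abs(est_b - self.pi.pi[i, b] * est_s)
        return x


def build_c_step(bulk: BulkProfile, rna: RnaCloneProfile, U_fixed: np.ndarray,
                 dims: ProblemDims, reg: Regularizers, cfg: DescentConfig,
                 pi: Optional[PiRatios] = None) -> CStepModel:
    """Assemble the C-step MILP with U fixed.

    Constraint groups (see module docstring): RNA-clone permutation M;
    L1 coupling of the segment block of C to M C_rna; rooted-binary-tree
    constraints on E with ancestry closure A; normal root genotype; c_max
    bounds; loss-supported Dollo placement (W, presence indicators);
    allele-gated breakpoint-vs-segment bounds (D); edge-activated tree cost R;
    and the breakpoint ratio cost S.
    """
    from .data_model import compute_pi

    n, m, l, g, r = dims.n, dims.m, dims.l, dims.g, dims.r
    n_mut, K, n_prime, root = dims.n_mut, dims.K, dims.n_prime, dims.root
    cmax = float(cfg.c_max)
    F = np.asarray(bulk.F, dtype=float)
    Q = np.asarray(bulk.Q)
    C_rna = np.asarray(rna.C_rna, dtype=float)
    if np.any(C_rna > cmax):
        import warnings
        warnings.warn("C_rna exceeds c_max; clipping", stacklevel=2)
        C_rna = np.clip(C_rna, 0, cmax)
    U = np.asarray(U_fixed, dtype=float)
    if pi is None:
        pi = compute_pi(bulk, c_max=cfg.c_max)

    model = LinearModel()
    C_idx = model.add_vars((n, K), lb=0.0, ub=cmax, integer=True)
    M_idx = model.add_vars((n, n), lb=0.0, ub=1.0, integer=True)
    E_idx = model.add_vars((n, n), lb=0.0, ub=1.0, integer=True)
    A_idx = model.add_vars((n, n), lb=0.0, ub=1.0, integer=True)
    W_idx = model.add_vars((n, n, n_mut), lb=0.0, ub=1.0, integer=True)
    D_idx = model.add_vars((n_mut,), lb=0.0, ub=1.0, integer=True)
    y_idx = model.add_vars((n, n_mut), lb=0.0, ub=1.0, integer=True)
    Cd_idx = model.add_vars((n, 2 * r), lb=0.0)       # |C' - M C_rna|
    Fd_idx = model.add_vars((m, K), lb=0.0)           # |F - U C|

    # (i) M is a permutation: each phylogeny clone <-> exactly one RNA clone
    for i in range(n):
        model.add_constraint(M_idx[i], np.ones(n), lb=1.0, ub=1.0)
        model.add_constraint(M_idx[:, i], np.ones(n), lb=1.0, ub=1.0)

    # (ii)+(iii) RNA-distance helpers on the segment block of C (C' aliased)
    for i in range(n):
        for j in range(2 * r):
            cols = np.concatenate(([Cd_idx[i, j], C_idx[i, n_mut + j]], M_idx[i]))
            model.add_constraint(cols, np.concatenate(([1.0, -1.0], C_rna[:, j])), lb=0.0)
            model.add_constraint(cols, np.concatenate(([1.0, 1.0], -C_rna[:, j])), lb=0.0)

    # (iv) rooted binary tree on E: no edge into the root, none out of leaves,
    # no self-loops; in-degree 1 off the root; out-degree <= 2; internal
    # nodes (and the root) have at least one child.
    model.fix(E_idx[:, root], 0.0)
    model.fix(np.diag(E_idx), 0.0)
    if n_prime:
        model.fix(E_idx[:n_prime, :], 0.0)
    for j in range(n):
        if j == root:
            continue
        model.add_constraint(E_idx[:, j], np.ones(n), lb=1.0, ub=1.0)
    for i in range(n_prime, n):
        model.add_constraint(E_idx[i], np.ones(n), lb=1.0, ub=2.0)

    # (v) ancestry closure: parents are ancestors and ancestry propagates
    # along edges; A[i,i] = 0 excludes cycles.
    model.fix(np.diag(A_idx), 0.0)
    for i in range(n):
        for j in range(n):
            model.add_constraint([A_idx[i, j], E_idx[i, j]], [1.0, -1.0], lb=0.0)
    for i in range(n_prime, n):            # only non-leaves can be parents
        for j in range(n):
            if j == i or j == root:
                continue
            for k in range(n):
                if k == i:
                    continue
                # A[k,j] >= A[k,i] + E[i,j] - 1  and  A[k,j] <= A[k,i] - E[i,j] + 1
                model.add_constraint(
                    [A_idx[k, j], A_idx[k, i], E_idx[i, j]], [1.0, -1.0, -1.0], lb=-1.0)
                model.add_constraint(
                    [A_idx[k, j], A_idx[k, i], E_idx[i, j]], [1.0, -1.0, 1.0], ub=1.0)

    # (vi) the root is the normal clone: no mutations, diploid segments
    model.fix(C_idx[root, :n_mut], 0.0)
    model.fix(C_idx[root, n_mut:], 1.0)

    # (viii) loss-supported Dollo: presence y tracks C>=1 on mutation columns;
    # every mutation is gained on exactly one tree edge; presence appears only
    # at the gain edge and persists only down unbroken carrier lineages.
    edges_allowed = [(i, j) for i in range(n_prime, n) for j in range(n)
                     if j != i and j != root]
    for k in range(n_mut):
        model.add_constraint(W_idx[:, :, k], np.ones((n, n)), lb=1.0, ub=1.0)
    for i in range(n):
        for j in range(n):
            if (i, j) not in set(edges_allowed):
                model.fix(W_idx[i, j, :], 0.0)
    model.fix(y_idx[root], 0.0)
    for i in range(n):
        for k in range(n_mut):
            # y = 1  <=>  C >= 1
            model.add_constraint([C_idx[i, k], y_idx[i, k]], [1.0, -cmax], ub=0.0)
            model.add_constraint([y_idx[i, k], C_idx[i, k]], [1.0, -1.0], ub=0.0)
    for (i, j) in edges_allowed:
        for k in range(n_mut):
            model.add_constraint([W_idx[i, j, k], E_idx[i, j]], [1.0, -1.0], ub=0.0)
            # y[j,k] <= y[i,k] + W[i,j,k] + (1 - E[i,j])
            model.add_constraint(
                [y_idx[j, k], y_idx[i, k], W_idx[i, j, k], E_idx[i, j]],
                [1.0, -1.0, -1.0, 1.0], ub=1.0)

    # (ix) allele-gated coupling: a mutation's copy number cannot exceed the
    # copy number of its D-selected allele of its segment.
    seg_of = np.argmax(Q, axis=1)
    seg1_cols = n_mut + seg_of
    seg2_cols = n_mut + r + seg_of
    for i in range(n):
        for b in range(n_mut):
            # C[i,b] <= C[i, seg1(b)] + (1 - D[b]) * cmax
            model.add_constraint(
                [C_idx[i, b], C_idx[i, seg1_cols[b]], D_idx[b]],
                [1.0, -1.0, cmax], ub=cmax)
            # C[i,b] <= C[i, seg2(b)] + D[b] * cmax
            model.add_constraint(
                [C_idx[i, b], C_idx[i, seg2_cols[b]], D_idx[b]],
                [1.0, -1.0, -cmax], ub=0.0)

    # (x) tree cost R: per-edge L1 segment-copy distance, big-M activated
    rho_idx = model.add_vars((len(edges_allowed), 2 * r), lb=0.0)
    for e, (i, j) in enumerate(edges_allowed):
        for s in range(2 * r):
            ci, cj = C_idx[i, n_mut + s], C_idx[j, n_mut + s]
            model.add_constraint(
                [rho_idx[e, s], ci, cj, E_idx[i, j]], [1.0, -1.0, 1.0, -cmax], lb=-cmax)
            model.add_constraint(
                [rho_idx[e, s], ci, cj, E_idx[i, j]], [1.0, 1.0, -1.0, -cmax], lb=-cmax)

    # (xi) ratio cost S over breakpoints (optionally SNVs) with valid pi
    n_ratio = l + (g if cfg.include_snv_ratio else 0)
    sigma_entries = []
    sigma_idx = []
    for i in range(m):
        for b in range(n_ratio):
            if b < l and not pi.valid[i, b]:
                continue
            if b >= l:
                continue  # SNV ratios require pi columns beyond l; not computed
            s_idx = int(model.add_vars((), lb=0.0))
            coefs_b = U[i]
            coefs_s = -pi.pi[i, b] * U[i]
            cols = np.concatenate(
                ([s_idx], C_idx[:, b], C_idx[:, seg1_cols[b]], C_idx[:, seg2_cols[b]]))
            co = np.concatenate(([1.0], coefs_b, coefs_s, coefs_s))
            model.add_constraint(cols, co, lb=0.0)
            model.add_constraint(cols, np.concatenate(([1.0], -coefs_b, -coefs_s, -coefs_s)), lb=0.0)
            sigma_entries.append((i, b))
            sigma_idx.append(s_idx)
    sigma_idx = np.asarray(sigma_idx, dtype=int)

    # F-residual helpers |F - U C| with U fixed
    for i in range(m):
        for k in range(K):
            cols = np.concatenate(([Fd_idx[i, k]], C_idx[:, k]))
            model.add_constraint(cols, np.concatenate(([1.0], U[i])), lb=F[i, k])
            model.add_constraint(cols, np.concatenate(([1.0], -U[i])), lb=-F[i, k])

    model.add_objective(Fd_idx, 1.0)
    model.add_objective(Cd_idx, 1.0)
    model.add_objective(rho_idx, reg.lambda1)
    if len(sigma_idx):
        model.add_objective(sigma_idx, reg.lambda2)

    idx = {"C": C_idx, "M": M_idx, "E": E_idx, "A": A_idx, "W": W_idx,
           "D": D_idx, "y": y_idx, "Cd": Cd_idx, "Fd": Fd_idx, "rho": rho_idx,
           "sigma": sigma_idx, "sigma_entries": sigma_entries,
           "seg_cols": (seg1_cols, seg2_cols)}
    var_counts = {"C": C_idx.size, "M": M_idx.size, "E": E_idx.size,
                  "A": A_idx.size, "W": W_idx.size, "D": D_idx.size,
                  "auxiliary": model.n_vars - (C_idx.size + M_idx.size + E_idx.size
                                               + A_idx.size + W_idx.size + D_idx.size)}
    return CStepModel(model=model, dims=dims, reg=reg, cfg=cfg, U=U,
                      C_rna=C_rna, F=F, Q=Q, pi=pi, idx=idx,
                      edges_allowed=edges_allowed, var_counts=var_counts)


def solve_c_step(cmodel: CStepModel, backend: Optional[SolverBackend] = None):
    """Solve the C-step MILP; returns ``(Solution, objective)``.

    The returned objective and term breakdown are recomputed from the rounded
    integer solution (not the solver's auxiliary variables), so they are exact
    for the reported matrices.
    """
    backend = backend or SolverBackend(time_limit_s=cmodel.cfg.time_limit_s,
                                       mip_gap=cmodel.cfg.mip_gap)
    res: MilpResult = cmodel.model.solve(backend)
    if res.x is None:
        raise InfeasibleError("C-step returned no incumbent: " + res.message)
    d = cmodel.dims
    x = res.x
    C = np.rint(x[cmodel.idx["C"]]).astype(int)
    M = np.rint(x[cmodel.idx["M"]]).astype(int)
    E = np.rint(x[cmodel.idx["E"]]).astype(int)
    A = np.rint(x[cmodel.idx["A"]]).astype(int)
    W = np.rint(x[cmodel.idx["W"]]).astype(int)
    D = np.rint(x[cmodel.idx["D"]]).astype(int)
    terms = objective_terms(cmodel.F, cmodel.U, C, M, cmodel.C_rna, E,
                            cmodel.pi, cmodel.Q, d, cmodel.reg)
    sol = Solution(U=cmodel.U.copy(), C=C, M=M, E=E, A=A, W=W, D=D,
                   objective=terms["total"], term_breakdown=terms,
                   gap=res.gap, timed_out=res.timed_out)
    return sol, terms["total"]


def objective_terms(F, U, C, M, C_rna, E, pi: PiRatios, Q, dims: ProblemDims,
                    reg: Regularizers) -> dict:
    """Evaluate the four objective addends at a concrete solution."""
    n_mut, l, r = dims.n_mut, dims.l, dims.r
    C = np.asarray(C, dtype=float)
    obj1 = float(np.abs(F - U @ C).sum())
    Cseg = C[:, n_mut:]
    obj2 = float(np.abs(Cseg - M @ np.asarray(C_rna, dtype=float)).sum())
    src, dst = np.nonzero(E)
    R = float(np.abs(Cseg[src] - Cseg[dst]).sum())
    S = 0.0
    if l:
        seg_of = np.argmax(np.asarray(Q)[:l], axis=1)
        est_b = U @ C[:, :l]
        est_s = U @ (C[:, n_mut + seg_of] + C[:, n_mut + r + seg_of])
        diff = np.abs(est_b - pi.pi * est_s)
        S = float(diff[pi.valid].sum())
    total = obj1 + obj2 + reg.lambda1 * R + reg.lambda2 * S
    return {"data_fit": obj1, "rna_fit": obj2, "R": R, "S": S,
            "total": total,
            "residual": obj1 + obj2 + reg.lambda2 * S}
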