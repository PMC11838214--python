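"""Coordinate-descent orchestration.

Each restart draws a random row-stochastic U0 (uniform Dirichlet per sample),
then alternates: C-step (genotypes, tree, RNA-clone assignment with U fixed)
followed by U-step (mixture fractions with C fixed).  The C-step runs first
because U is the randomly initialized block.  The best solution over all
restarts by the final full objective is returned; ties break toward the
lowest restart index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import ilp_core
from ._milp import InfeasibleError, SolverBackend
from .data_model import (BulkProfile, DescentConfig, RnaCloneProfile,
                         Solution, compute_pi, resolve_regularizers,
                         validate_problem)


@dataclass
class DescentTrace:
    """Per-iteration objective bookkeeping across restarts."""

    restarts: list = field(default_factory=list)  # list of list of dicts
    final_solutions: list = field(default_factory=list)  # per-restart Solution or None
    best_restart: int = -1
    best_objective: float = np.inf

    def to_jsonl(self) -> str:
        import json
        lines = []
        for r, iters in enumerate(self.restarts):
            for entry in iters:
                lines.append(json.dumps({"restart": r, **entry}))
        return "\n".join(lines) + "\n"


def run(bulk: BulkProfile, rna: RnaCloneProfile, cfg: DescentConfig,
        early_stop_tol: Optional[float] = 1e-6):
    """Run the full coordinate descent; returns ``(Solution, DescentTrace)``."""
    dims = validate_problem(bulk, rna, cfg)
    reg = resolve_regularizers(dims, cfg)
    pi = compute_pi(bulk, c_max=cfg.c_max)
    seg_of = np.argmax(bulk.Q[:dims.l], axis=1) if dims.l else np.zeros(0, dtype=int)
    seg1 = dims.n_mut + seg_of
    seg2 = dims.n_mut + dims.r + seg_of
    rng = np.random.default_rng(cfg.seed)
    backend = SolverBackend(name=cfg.solver_name, time_limit_s=cfg.time_limit_s,
                            mip_gap=cfg.mip_gap)

    trace = DescentTrace()
    best_sol: Optional[Solution] = None
    failures = []
    for restart in range(cfg.num_restarts):
        U = rng.dirichlet(np.ones(cfg.n), size=dims.m)
        entries = []
        sol = None
        prev_total = np.inf
        try:
            for it in range(cfg.num_iterations):
                cmodel = ilp_core.build_c_step(bulk, rna, U, dims, reg, cfg, pi=pi)
                sol, _ = ilp_core.solve_c_step(cmodel, backend)
                U, obj1 = ilp_core.solve_u_step(
                    bulk.F, sol.C,
                    ratio=(pi.pi, pi.valid, seg1, seg2, reg.lambda2) if dims.l else None,
                    backend=backend)
                sol.U = U
                terms = ilp_core.objective_terms(
                    bulk.F, U, sol.C, sol.M, rna.C_rna, sol.E, pi, bulk.Q, dims, reg)
                sol.term_breakdown = terms
                sol.objective = terms["total"]
                entries.append({
                    "iteration": it, "objective": terms["total"],
                    "data_fit": terms["data_fit"], "rna_fit": terms["rna_fit"],
                    "R": terms["R"], "S": terms["S"],
                    "c_step_gap": sol.gap, "c_step_timed_out": sol.timed_out,
                })
                if early_stop_tol is not None and prev_total - terms["total"] < early_stop_tol:
                    break
                prev_total = terms["total"]
        except InfeasibleError as exc:  # pragma: no cover - contradictory inputs
            failures.append(f"restart {restart}: {exc}")
            trace.restarts.append(entries)
            trace.final_solutions.append(None)
            continue
        trace.restarts.append(entries)
        trace.final_solutions.append(sol)
        if sol is not None and sol.objective < trace.best_objective:
            trace.best_objective = sol.objective
            trace.best_restart = restart
            best_sol = sol
    if best_sol is None:
        raise InfeasibleError("all restarts failed: " + "; ".join(failures))
    return best_sol, trace
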