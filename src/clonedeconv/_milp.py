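"""Thin mixed-integer linear programming layer over scipy's HiGHS interface.

Collects variables, linear constraints and a linear objective incrementally,
then hands one sparse model to :func:`scipy.optimize.milp`.  Supports the
things the deconvolution ILPs need: binary/integer/continuous variables, L1
objectives through auxiliary variables, a wall-clock limit that returns the
incumbent, and post-hoc feasibility evaluation of an externally supplied
point (used to check planted simulator solutions against the constraint set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp


@dataclass
class SolverBackend:
    """Solver options; ``name`` is informational (HiGHS via scipy)."""

    name: str = "highs"
    time_limit_s: Optional[float] = None
    mip_gap: float = 1e-4
    threads: int = 1


@dataclass
class MilpResult:
    x: Optional[np.ndarray]
    objective: float
    status: int            # scipy milp status code (0 = optimal)
    success: bool
    timed_out: bool
    gap: float
    message: str = ""


class InfeasibleError(RuntimeError):
    """The model admits no feasible point."""


@dataclass
class LinearModel:
    _lb: list = field(default_factory=list)
    _ub: list = field(default_factory=list)
    _integer: list = field(default_factory=list)
    _obj: dict = field(default_factory=dict)
    _rows_i: list = field(default_factory=list)
    _rows_j: list = field(default_factory=list)
    _rows_v: list = field(default_factory=list)
    _row_lb: list = field(default_factory=list)
    _row_ub: list = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return len(self._lb)

    @property
    def n_constraints(self) -> int:
        return len(self._row_lb)

    def add_vars(self, shape, *, lb: float = 0.0, ub: float = np.inf,
                 integer: bool = False) -> np.ndarray:
        """Register a block of variables; returns their indices with ``shape``."""
        count = int(np.prod(shape)) if shape else 1
        start = self.n_vars
        self._lb.extend([lb] * count)
        self._ub.extend([ub] * count)
        self._integer.extend([1 if integer else 0] * count)
        return np.arange(start, start + count).reshape(shape)

    def fix(self, idx, value) -> None:
        """Pin variables to a constant via their bounds."""
        for i, v in np.broadcast(np.asarray(idx).ravel(), np.asarray(value).ravel()):
            self._lb[int(i)] = float(v)
            self._ub[int(i)] = float(v)

    def add_constraint(self, cols, coefs, *, lb: float = -np.inf, ub: float = np.inf) -> None:
        row = self.n_constraints
        cols = np.asarray(cols).ravel()
        coefs = np.asarray(coefs, dtype=float).ravel()
        self._rows_i.extend([row] * len(cols))
        self._rows_j.extend(int(c) for c in cols)
        self._rows_v.extend(float(v) for v in coefs)
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def add_objective(self, cols, coefs=1.0) -> None:
        cols = np.asarray(cols).ravel()
        coefs = np.broadcast_to(np.asarray(coefs, dtype=float), cols.shape)
        for c, v in zip(cols, coefs):
            self._obj[int(c)] = self._obj.get(int(c), 0.0) + float(v)

    # -- assembly -----------------------------------------------------------

    def _matrices(self):
        A = sparse.coo_matrix(
            (self._rows_v, (self._rows_i, self._rows_j)),
            shape=(self.n_constraints, self.n_vars)).tocsr()
        c = np.zeros(self.n_vars)
        for j, v in self._obj.items():
            c[j] = v
        return A, c

    def objective_at(self, x: np.ndarray) -> float:
        _, c = self._matrices()
        return float(c @ x)

    def max_violation(self, x: np.ndarray) -> float:
        """Largest constraint/bound violation at ``x`` (0 means feasible)."""
        A, _ = self._matrices()
        ax = A @ x
        viol = 0.0
        viol = max(viol, float(np.max(np.asarray(self._row_lb) - ax, initial=0.0)))
        viol = max(viol, float(np.max(ax - np.asarray(self._row_ub), initial=0.0)))
        viol = max(viol, float(np.max(np.asarray(self._lb) - x, initial=0.0)))
        viol = max(viol, float(np.max(x - np.asarray(self._ub), initial=0.0)))
        return viol

    def solve(self, backend: Optional[SolverBackend] = None) -> MilpResult:
        backend = backend or SolverBackend()
        A, c = self._matrices()
        options = {"presolve": True}
        if backend.time_limit_s is not None:
            options["time_limit"] = float(backend.time_limit_s)
        if any(self._integer):
            options["mip_rel_gap"] = backend.mip_gap
        constraints = []
        if self.n_constraints:
            constraints.append(LinearConstraint(A, self._row_lb, self._row_ub))
        res = milp(
            c,
            constraints=constraints,
            integrality=np.asarray(self._integer),
            bounds=Bounds(np.asarray(self._lb, dtype=float),
                          np.asarray(self._ub, dtype=float)),
            options=options,
        )
        timed_out = res.status == 1
        if res.status == 2:
            raise InfeasibleError(res.message)
        if res.x is None:
            # time limit hit before any incumbent, or solver failure
            return MilpResult(x=None, objective=np.inf, status=res.status,
                              success=False, timed_out=timed_out, gap=np.inf,
                              message=res.message)
        gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
        return MilpResult(x=np.asarray(res.x), objective=float(c @ res.x),
                          status=int(res.status), success=bool(res.success),
                          timed_out=timed_out, gap=gap, message=res.message)

    def write_lp(self, path) -> None:
        """Dump the model in a plain LP-like text form for debugging."""
        A, c = self._matrices()
        A = A.tocoo()
        lines = ["\\ model dump", "min: " + " + ".join(
            f"{v:g} x{j}" for j, v in sorted(self._obj.items()))]
        rows: dict = {}
        for i, j, v in zip(A.row, A.col, A.data):
            rows.setdefault(i, []).append(f"{v:+g} x{j}")
        for i in range(self.n_constraints):
            expr = " ".join(rows.get(i, ["0"]))
            lines.append(f"r{i}: {self._row_lb[i]:g} <= {expr} <= {self._row_ub[i]:g}")
        for j in range(self.n_vars):
            kind = "int" if self._integer[j] else "cont"
            lines.append(f"b{j}: {self._lb[j]:g} <= x{j} <= {self._ub[j]:g} ({kind})")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
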