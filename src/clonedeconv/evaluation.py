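"""Clone-matched accuracy metrics (RMSE of frequencies and genotypes).

Estimated clones carry arbitrary labels, so truth and estimate are aligned by
an optimal assignment on genotype L1 distance before any error is computed;
the same permutation is applied jointly to U and C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_model import Solution
from .simulator import SimTruth


@dataclass
class EvalReport:
    rmse_U: float
    rmse_C_snv: float
    rmse_C_sv: float
    matching: np.ndarray            # est clone index aligned to each true clone
    breakdown: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"rmse_U": self.rmse_U, "rmse_C_snv": self.rmse_C_snv,
                "rmse_C_sv": self.rmse_C_sv,
                "matching": [int(i) for i in self.matching],
                **{k: float(v) for k, v in self.breakdown.items()}}


def match_clones(C_true: np.ndarray, C_est: np.ndarray) -> np.ndarray:
    """Permutation aligning estimated clones to true clones.

    Returns ``perm`` with ``C_est[perm[i]]`` matched to ``C_true[i]``,
    minimizing total L1 genotype distance (Hungarian assignment).
    """
    C_true = np.asarray(C_true, dtype=float)
    C_est = np.asarray(C_est, dtype=float)
    if C_true.shape != C_est.shape:
        raise ValueError("genotype matrices must have identical shapes")
    cost = np.abs(C_true[:, None, :] - C_est[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0:
        return 0.0
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_report(truth: SimTruth, sol: Solution) -> EvalReport:
    """Clone-matched RMSEs of mixture fractions and SV/SNV genotypes."""
    d = truth.dims
    if sol.C.shape != truth.C.shape or sol.U.shape != truth.U.shape:
        raise ValueError("truth and solution dimensions disagree")
    perm = match_clones(truth.C, sol.C)
    U_est = sol.U[:, perm]
    C_est = sol.C[perm]
    rep = EvalReport(
        rmse_U=_rmse(truth.U, U_est),
        rmse_C_snv=_rmse(truth.C[:, d.l:d.n_mut], C_est[:, d.l:d.n_mut]),
        rmse_C_sv=_rmse(truth.C[:, :d.l], C_est[:, :d.l]),
        matching=perm,
        breakdown={
            "rmse_C_segments": _rmse(truth.C[:, d.n_mut:], C_est[:, d.n_mut:]),
            "rmse_C_all": _rmse(truth.C, C_est),
            "assignment_cost": float(
                np.abs(truth.C - C_est).sum()),
        },
    )
    return rep
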