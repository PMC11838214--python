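"""Typed containers and validation for the deconvolution problem.

The method decomposes ``m`` bulk DNA-seq samples into ``n`` clones related by
a rooted binary phylogeny, guided by allele-specific segmental copy numbers
called from scRNA-seq clones.  All matrices follow one column convention:

    [ l breakpoint ends | g SNVs | r allele-1 segments | r allele-2 segments ]

so the bulk variant matrix ``F`` is ``m x (l+g+2r)`` and clone genotypes ``C``
are ``n x (l+g+2r)``.  Node ordering in the phylogeny is fixed: clones
``1..n'`` (0-based ``0..n'-1``) are leaves, ``n'+1..n-1`` are internal, and
clone ``n`` (0-based ``n-1``) is the root, which represents the normal
(mutation-free, diploid) cell population.  ``n' = (n-1)/2`` so ``n`` must be
odd and at least 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


@dataclass(frozen=True)
class ProblemDims:
    """Problem sizes.

    n: clone count (user set, odd, >= 3); m: samples; l: SV breakpoint ends
    (even; ends come in mated pairs); g: SNVs; r: genomic segments.
    """

    n: int
    m: int
    l: int
    g: int
    r: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError(f"n must be >= 3, got {self.n}")
        if self.n % 2 == 0:
            raise ValidationError(f"n must be odd, got {self.n}")
        if self.l % 2 != 0:
            raise ValidationError(f"l must be even (paired breakpoint ends), got {self.l}")
        if self.m < 1 or self.g < 1 or self.r < 1:
            raise ValidationError("m, g and r must all be >= 1")

    @property
    def n_prime(self) -> int:
        """Number of leaves (= number of non-root internal nodes + ... = (n-1)/2)."""
        return (self.n - 1) // 2

    @property
    def n_mut(self) -> int:
        """Number of mutation columns (breakpoints + SNVs)."""
        return self.l + self.g

    @property
    def K(self) -> int:
        """Total column count l + g + 2r."""
        return self.l + self.g + 2 * self.r

    @property
    def root(self) -> int:
        """0-based index of the root (normal) clone."""
        return self.n - 1

    def seg_col(self, s: int, allele: int) -> int:
        """0-based column of segment ``s`` (0-based), allele 0 or 1."""
        return self.n_mut + allele * self.r + s


@dataclass
class BulkProfile:
    """Bulk DNA-seq input: average copy numbers plus breakpoint topology.

    F : (m, l+g+2r) nonnegative floats, average copy number of each variant
        column in each sample.
    Q : (l+g, r) one-hot map of each breakpoint end / SNV to its segment.
    G : (l, l) symmetric zero-diagonal perfect matching of breakpoint ends.
    variant_ids : per-column metadata for the l+g mutation columns (free-form
        records: chrom, pos, kind, ...).  Optional for in-memory use.
    """

    F: np.ndarray
    Q: np.ndarray
    G: np.ndarray
    l: int
    g: int
    r: int
    variant_ids: Optional[Sequence[dict]] = None
    sample_ids: Optional[Sequence[str]] = None

    @property
    def m(self) -> int:
        return self.F.shape[0]

    def validate(self) -> None:
        l, g, r = self.l, self.g, self.r
        K = l + g + 2 * r
        if self.F.ndim != 2 or self.F.shape[1] != K:
            raise ValidationError(
                f"F must be m x (l+g+2r) = m x {K}, got {self.F.shape}")
        if np.any(self.F < 0):
            raise ValidationError("F must be nonnegative")
        if self.Q.shape != (l + g, r):
            raise ValidationError(f"Q must be {(l + g, r)}, got {self.Q.shape}")
        if not np.isin(self.Q, (0, 1)).all():
            raise ValidationError("Q must be binary")
        if not np.all(self.Q.sum(axis=1) == 1):
            raise ValidationError("each row of Q must be one-hot (variant in exactly one segment)")
        if self.G.shape != (l, l):
            raise ValidationError(f"G must be {(l, l)}, got {self.G.shape}")
        if l:
            if not np.isin(self.G, (0, 1)).all():
                raise ValidationError("G must be binary")
            if np.any(np.diag(self.G) != 0):
                raise ValidationError("G must have zero diagonal")
            if not np.array_equal(self.G, self.G.T):
                raise ValidationError("G must be symmetric")
            if not np.all(self.G.sum(axis=1) == 1):
                raise ValidationError("unpaired breakpoint: each row of G must sum to 1")


@dataclass
class RnaCloneProfile:
    """Allele-specific segmental copy numbers of the n scRNA-seq clones.

    C_rna : (n, 2r) nonnegative integers, same segment/allele column
        convention as the segment block of F.
    """

    C_rna: np.ndarray
    clone_labels: Optional[Sequence[str]] = None

    @property
    def n(self) -> int:
        return self.C_rna.shape[0]

    def validate(self, r: Optional[int] = None) -> None:
        if self.C_rna.ndim != 2:
            raise ValidationError("C_rna must be 2-D")
        if r is not None and self.C_rna.shape[1] != 2 * r:
            raise ValidationError(
                f"C_rna must have 2r = {2 * r} columns, got {self.C_rna.shape[1]}")
        if self.C_rna.shape[1] % 2 != 0:
            raise ValidationError("C_rna must have an even column count (two alleles)")
        if np.any(self.C_rna < 0):
            raise ValidationError("C_rna must be nonnegative")
        if not np.all(self.C_rna == np.rint(self.C_rna)):
            raise ValidationError("C_rna must be integral (round caller output first)")


@dataclass
class DescentConfig:
    """Knobs of the coordinate-descent solver.

    n            : clone count to fit (odd, >= 3).
    num_restarts : independent random initializations of U (best kept).
    num_iterations : coordinate-descent sweeps per restart (C-step then U-step).
    time_limit_s : wall-clock budget per ILP solve; the incumbent is used on
                   timeout.  None = no limit.
    c_max        : upper bound on any clonal copy number; also the big-M
                   constant in the linearizations.
    lambda1/lambda2 : regularizer weights; None = the size-ratio formulas.
    sv_cap/snv_cap  : optional subsampling caps applied at I/O time.
    """

    n: int
    num_restarts: int = 3
    num_iterations: int = 3
    time_limit_s: Optional[float] = None
    c_max: int = 10
    lambda1: Optional[float] = None
    lambda2: Optional[float] = None
    seed: int = 0
    sv_cap: Optional[int] = None
    snv_cap: Optional[int] = None
    solver_name: str = "highs"
    mip_gap: float = 1e-4
    include_snv_ratio: bool = False  # include SNV columns in the S ratio term

    def __post_init__(self) -> None:
        if self.num_restarts < 1 or self.num_iterations < 1:
            raise ValidationError("num_restarts and num_iterations must be positive")
        if self.c_max < 2:
            raise ValidationError("c_max must be >= 2")
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class Regularizers:
    """Weights of the tree cost R and the CNA-SV consistency cost S."""

    lambda1: float
    lambda2: float
    R_value: Optional[float] = None
    S_value: Optional[float] = None


@dataclass
class PiRatios:
    """Observed breakpoint-to-segment mixture copy-number ratios.

    pi[i, b] = F[i, b] / (F[i, seg(b), allele 1] + F[i, seg(b), allele 2]).
    Entries with a zero denominator carry no information; they are flagged in
    ``valid`` and excluded from the S term.
    """

    pi: np.ndarray
    valid: np.ndarray  # boolean mask, same shape


@dataclass
class Solution:
    """One deconvolution result.

    U : (m, n) mixture fractions, rows on the simplex.
    C : (n, l+g+2r) integer clone genotypes; ``C_prime`` is a view of the
        segment block.
    M : (n, n) permutation mapping phylogeny clones to RNA clones.
    E, A : (n, n) binary tree adjacency and its ancestry (reachability) closure.
    W : (n, n, l+g) binary gain-edge placement of each mutation.
    D : (l+g,) binary allele assignment (1 = first allele).
    """

    U: np.ndarray
    C: np.ndarray
    M: np.ndarray
    E: np.ndarray
    A: np.ndarray
    W: np.ndarray
    D: np.ndarray
    objective: float
    term_breakdown: dict = field(default_factory=dict)
    gap: float = 0.0
    timed_out: bool = False

    @property
    def C_prime(self) -> np.ndarray:
        n_mut = self.W.shape[2]
        return self.C[:, n_mut:]


def validate_problem(bulk: BulkProfile, rna: RnaCloneProfile, cfg: DescentConfig) -> ProblemDims:
    """Cross-validate the three inputs and return consistent dimensions.

    Idempotent and side-effect free; raises :class:`ValidationError` with a
    specific message on the first violated invariant.
    """
    if bulk.F.size == 0 or rna.C_rna.size == 0:
        raise ValidationError("empty input matrix")
    bulk.validate()
    rna.validate(r=bulk.r)
    dims = ProblemDims(n=cfg.n, m=bulk.m, l=bulk.l, g=bulk.g, r=bulk.r)
    if rna.n != cfg.n:
        raise ValidationError(
            f"C_rna has {rna.n} clones but the configuration requests n={cfg.n}")
    if np.any(rna.C_rna > cfg.c_max):
        raise ValidationError(
            f"C_rna exceeds c_max={cfg.c_max}; raise c_max or clip the profile")
    return dims


def compute_lambdas(dims: ProblemDims) -> Regularizers:
    """Size-ratio defaults for the regularizer weights.

    lambda1 = (1/2) * (l+g+2r)*m / (2r*n) — the ratio of the entry count of
    the bulk data-fit term to that of the tree cost R (R spans ~n edges of 2r
    segment columns).  lambda2 = (1/2) * (l+g+2r) / (l+g), the analogous ratio
    for the breakpoint-consistency cost S.
    """
    lam1 = 0.5 * (dims.K * dims.m) / (2 * dims.r * dims.n)
    lam2 = 0.5 * dims.K / (dims.l + dims.g)
    return Regularizers(lambda1=lam1, lambda2=lam2)


def resolve_regularizers(dims: ProblemDims, cfg: DescentConfig) -> Regularizers:
    """Apply user overrides on top of the default formulas."""
    reg = compute_lambdas(dims)
    if cfg.lambda1 is not None:
        reg = replace(reg, lambda1=cfg.lambda1)
    if cfg.lambda2 is not None:
        reg = replace(reg, lambda2=cfg.lambda2)
    return reg


def compute_pi(bulk: BulkProfile, c_max: Optional[int] = None) -> PiRatios:
    """Observed breakpoint/segment copy-number ratios (m x l).

    The segment of breakpoint ``b`` is located through Q; 0/0 entries are
    flagged invalid rather than clamped.  With ``c_max`` given, valid entries
    are clipped into [0, c_max].
    """
    m, l = bulk.m, bulk.l
    pi = np.zeros((m, l))
    valid = np.zeros((m, l), dtype=bool)
    if l == 0:
        return PiRatios(pi=pi, valid=valid)
    seg_of = np.argmax(bulk.Q[:l], axis=1)
    n_mut = bulk.l + bulk.g
    denom = (bulk.F[:, n_mut + seg_of] + bulk.F[:, n_mut + bulk.r + seg_of])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bulk.F[:, :l] / denom
    valid = denom > 0
    pi[valid] = ratio[valid]
    if c_max is not None:
        pi = np.clip(pi, 0.0, float(c_max))
    return PiRatios(pi=pi, valid=valid)
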