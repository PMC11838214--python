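"""Ground-truthed synthetic instance generator.

Emulates the evaluation protocol of the method: a random rooted binary clonal
tree whose root is the normal diploid clone; SNVs at uniform genomic
positions; SVs with Poisson-distributed lengths (mean 5,745,000 bp, the
TCGA-BRCA average) and event types drawn with relative weights 2:1:2:1 for
amplification : inversion : deletion : translocation; bulk read-count noise
from per-segment Poisson depths (mean 50) feeding binomial variant read
counts; and allele-specific scRNA segment profiles from per-gene Poisson
transcript counts (mean 50 per gene for a diploid segment, 3-6 genes per
segment) averaged and renormalized so the diploid state maps to copy number
1 per allele.

Genomic coordinates live on two chromosome templates with the GRCh38 chr1 and
chr2 lengths, pre-partitioned into ``r`` contiguous equal-width segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import BulkProfile, ProblemDims, RnaCloneProfile
from .ilp_core import ancestry_closure

CHROM_TEMPLATES = (("chr1", 248_956_422), ("chr2", 242_193_529))

EVENT_KINDS = ("amplification", "inversion", "deletion", "translocation")


@dataclass
class SimConfig:
    """Study conditions of the synthetic protocol (defaults = the protocol)."""

    n: int = 3                       # clones, odd, >= 3 (root = normal)
    m: int = 2                       # bulk samples (protocol: two per patient)
    g: int = 40                      # SNVs
    n_svs: int = 80                  # SVs (=> l = 2 * n_svs breakpoint ends)
    r: int = 6                       # genomic segments over the two templates
    sv_length_mean: float = 5_745_000.0
    cna_event_weights: tuple = (2.0, 1.0, 2.0, 1.0)  # amp : inv : del : tra
    depth_mean: float = 50.0         # bulk per-segment read depth
    transcript_mean: float = 50.0    # per-gene transcripts, diploid segment
    genes_per_segment: tuple = (3, 6)
    sc_total_depth: float = 120.0    # single-cell per-site total read depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("n must be odd and >= 3")
        if min(self.m, self.g, self.n_svs, self.r) < 1:
            raise ValueError("m, g, n_svs, r must be positive")
        if any(w < 0 for w in self.cna_event_weights) or sum(self.cna_event_weights) <= 0:
            raise ValueError("event weights must be nonnegative with positive sum")
        for v in (self.sv_length_mean, self.depth_mean, self.transcript_mean,
                  self.sc_total_depth):
            if v <= 0:
                raise ValueError("all means must be positive")

    @property
    def l(self) -> int:
        return 2 * self.n_svs


@dataclass
class SimTruth:
    """Everything the generator knows: tree, genotypes, frequencies, noise-free F."""

    cfg: SimConfig
    dims: ProblemDims
    E: np.ndarray                    # (n, n) true tree
    A: np.ndarray                    # ancestry closure of E
    C: np.ndarray                    # (n, l+g+2r) true genotypes
    U: Optional[np.ndarray] = None   # (m, n) true mixture fractions
    W: Optional[np.ndarray] = None   # (n, n, l+g) gain-edge placement
    D: Optional[np.ndarray] = None   # (l+g,) allele assignment
    Q: Optional[np.ndarray] = None
    G: Optional[np.ndarray] = None
    F0: Optional[np.ndarray] = None  # noise-free U @ C
    segments: list = field(default_factory=list)   # (chrom, start, end) per segment
    variants: list = field(default_factory=list)   # per-mutation metadata dicts
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary samplers (exposed for calibration checks)
# ---------------------------------------------------------------------------

def draw_segment_depths(size: int, mean: float = 50.0, rng=None) -> np.ndarray:
    """Per-segment bulk read depths ~ Poisson(mean), zero redrawn."""
    rng = np.random.default_rng(rng)
    d = rng.poisson(mean, size=size)
    while np.any(d == 0):
        zero = d == 0
        d[zero] = rng.poisson(mean, size=int(zero.sum()))
    return d


def draw_sv_lengths(size: int, mean: float = 5_745_000.0, rng=None) -> np.ndarray:
    """Structural-variant lengths ~ Poisson(mean) in bp."""
    rng = np.random.default_rng(rng)
    return rng.poisson(mean, size=size)


def draw_event_kinds(size: int, weights=(2.0, 1.0, 2.0, 1.0), rng=None) -> np.ndarray:
    """Event-type indices into EVENT_KINDS with the 2:1:2:1 default weights."""
    rng = np.random.default_rng(rng)
    p = np.asarray(weights, dtype=float)
    return rng.choice(len(p), size=size, p=p / p.sum())


def draw_transcript_counts(n_genes: int, cn=(1, 1), mean: float = 50.0,
                           rng=None) -> np.ndarray:
    """Per-gene total transcript counts, (n_genes, 2) per-allele draws.

    Each allele contributes Poisson(mean * cn_allele / 2) transcripts, so a
    diploid segment (cn = (1, 1)) averages ``mean`` transcripts per gene.
    """
    rng = np.random.default_rng(rng)
    lam = mean * np.asarray(cn, dtype=float) / 2.0
    return rng.poisson(np.broadcast_to(lam, (n_genes, 2)))


def simulate_sc_reads(bafs: np.ndarray, total_depth: float = 120.0, rng=None):
    """Single-cell per-site (ref, alt) read counts at clonal B-allele fractions.

    Total depth per site ~ Poisson(total_depth); alternate reads binomial at
    the clonal BAF.  This is the error-free single-cell SNV read generator of
    the comparison protocol.
    """
    rng = np.random.default_rng(rng)
    bafs = np.asarray(bafs, dtype=float)
    total = rng.poisson(total_depth, size=bafs.shape)
    alt = rng.binomial(total, np.clip(bafs, 0.0, 1.0))
    return total - alt, alt


# ---------------------------------------------------------------------------
# tree + genotypes
# ---------------------------------------------------------------------------

def simulate_tree(n: int, rng=None) -> np.ndarray:
    """Random rooted binary tree honoring the node-ordering convention.

    Leaves are nodes 0..n'-1, internal nodes n'..n-2, root n-1 (0-based),
    n' = (n-1)/2.  Every internal node keeps >= 1 child and <= 2 children.
    """
    rng = np.random.default_rng(rng)
    n_prime = (n - 1) // 2
    root = n - 1
    internal = list(range(n_prime, n - 1))
    E = np.zeros((n, n), dtype=int)
    capacity = {root: 2}
    placed = [root]
    for v in internal:
        candidates = [p for p in placed if capacity[p] > 0]
        p = int(rng.choice(candidates))
        E[p, v] = 1
        capacity[p] -= 1
        capacity[v] = 2
        placed.append(v)
    childless = [v for v in placed if capacity[v] == 2 and E[v].sum() == 0]
    leaves = list(range(n_prime))
    rng.shuffle(leaves)
    for v in childless:
        leaf = leaves.pop()
        E[v, leaf] = 1
        capacity[v] -= 1
    for leaf in leaves:
        candidates = [p for p in placed if capacity[p] > 0]
        p = int(rng.choice(candidates))
        E[p, leaf] = 1
        capacity[p] -= 1
    return E


def _make_segments(r: int) -> list:
    """Pre-partition the chromosome templates into r contiguous bins."""
    total = sum(length for _, length in CHROM_TEMPLATES)
    counts = []
    for i, (_, length) in enumerate(CHROM_TEMPLATES):
        if r == 1:
            counts = [1, 0]
            break
        c = max(1, round(r * length / total))
        counts.append(c)
    while sum(counts) > r:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < r:
        counts[int(np.argmin(counts))] += 1
    segments = []
    for (chrom, length), c in zip(CHROM_TEMPLATES, counts):
        bounds = np.linspace(0, length, c + 1, dtype=np.int64)
        for s in range(c):
            segments.append((chrom, int(bounds[s]), int(bounds[s + 1])))
    return segments


def _segment_of(segments, chrom: str, pos: int) -> int:
    for s, (c, start, end) in enumerate(segments):
        if c == chrom and start <= pos < end:
            return s
    raise ValueError(f"position {chrom}:{pos} outside all segments")


def simulate_tree_and_genotypes(cfg: SimConfig, rng=None) -> SimTruth:
    """Plant the tree, mutation placements and the integer genotype matrix.

    Amplifications/deletions shift the affected allele's copy number by +-1
    over the carrier subtree (an allele lost to zero can never be regained,
    so genotypes respect loss-supported Dollo); inversions and translocations
    are copy-neutral.  Breakpoint and SNV copy numbers equal the copy number
    of their segment's assigned allele within the carrier subtree, so the
    allele-gated coupling constraint holds with equality.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    n, g, r = cfg.n, cfg.g, cfg.r
    l = cfg.l
    dims = ProblemDims(n=n, m=cfg.m, l=l, g=g, r=r)
    E = simulate_tree(n, rng)
    A = ancestry_closure(E)
    edges = list(zip(*np.nonzero(E)))
    segments = _make_segments(r)
    chrom_lengths = dict(CHROM_TEMPLATES)
    chrom_names = [c for c, _ in CHROM_TEMPLATES]
    chrom_p = np.asarray([ln for _, ln in CHROM_TEMPLATES], dtype=float)
    chrom_p /= chrom_p.sum()

    # --- draw events -------------------------------------------------------
    sv_kinds = draw_event_kinds(cfg.n_svs, cfg.cna_event_weights, rng)
    sv_lengths = draw_sv_lengths(cfg.n_svs, cfg.sv_length_mean, rng)
    events = []
    variants = []   # one dict per mutation column (l breakpoints then g SNVs)
    for k in range(cfg.n_svs):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        clen = chrom_lengths[chrom]
        start = int(rng.integers(0, clen - 2))
        end = int(min(start + max(int(sv_lengths[k]), 1), clen - 1))
        kind = EVENT_KINDS[int(sv_kinds[k])]
        if kind == "translocation":
            mate_chrom = chrom_names[(chrom_names.index(chrom) + 1) % len(chrom_names)]
            mate_pos = int(rng.integers(0, chrom_lengths[mate_chrom] - 1))
            ends = [(chrom, start), (mate_chrom, mate_pos)]
        else:
            ends = [(chrom, start), (chrom, end)]
        allele = int(rng.integers(2))
        edge = edges[int(rng.integers(len(edges)))]
        affected = []
        if kind in ("amplification", "deletion"):
            affected = [s for s, (c, s0, s1) in enumerate(segments)
                        if c == chrom and s0 < end and start < s1]
        events.append({"kind": kind, "allele": allele, "edge": edge,
                       "segments": affected, "sv_id": k})
        for e_i, (c, p) in enumerate(ends):
            variants.append({"kind": "breakpoint", "chrom": c, "pos": p,
                             "sv_id": k, "end": e_i, "sv_type": kind,
                             "allele": allele, "edge": edge,
                             "mate_chrom": ends[1 - e_i][0],
                             "mate_pos": ends[1 - e_i][1]})
    for _ in range(g):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        pos = int(rng.integers(0, chrom_lengths[chrom] - 1))
        allele = int(rng.integers(2))
        edge = edges[int(rng.integers(len(edges)))]
        variants.append({"kind": "snv", "chrom": chrom, "pos": pos,
                         "allele": allele, "edge": edge})

    # --- Q and G -----------------------------------------------------------
    n_mut = l + g
    Q = np.zeros((n_mut, r), dtype=int)
    for b, v in enumerate(variants):
        Q[b, _segment_of(segments, v["chrom"], v["pos"])] = 1
    G = np.zeros((l, l), dtype=int)
    for k in range(cfg.n_svs):
        G[2 * k, 2 * k + 1] = G[2 * k + 1, 2 * k] = 1

    # --- segment allele copy numbers, events applied root-down -------------
    depth = np.zeros(n, dtype=int)
    order = [n - 1]
    while order and len(order) < n:
        for p in list(order):
            for c in np.nonzero(E[p])[0]:
                if c not in order:
                    depth[c] = depth[p] + 1
                    order.append(c)
    seg_cn = np.ones((n, 2 * r), dtype=int)
    carriers = {}
    for (p, c) in edges:
        below = {c} | set(np.nonzero(A[c])[0])
        carriers[(p, c)] = sorted(below)
    cn_events = [ev for ev in events if ev["kind"] in ("amplification", "deletion")]
    cn_events.sort(key=lambda ev: depth[ev["edge"][1]])
    for ev in cn_events:
        delta = 1 if ev["kind"] == "amplification" else -1
        for s in ev["segments"]:
            col = ev["allele"] * r + s
            for p in carriers[ev["edge"]]:
                cur = seg_cn[p, col]
                if delta > 0 and cur >= 1:
                    seg_cn[p, col] = cur + 1
                elif delta < 0:
                    seg_cn[p, col] = max(cur - 1, 0)

    # --- mutation copy numbers and gain placements -------------------------
    C = np.zeros((n, n_mut + 2 * r), dtype=int)
    C[:, n_mut:] = seg_cn
    W = np.zeros((n, n, n_mut), dtype=int)
    D = np.zeros(n_mut, dtype=int)
    seg_of = np.argmax(Q, axis=1)
    for b, v in enumerate(variants):
        p_edge = v["edge"]
        W[p_edge[0], p_edge[1], b] = 1
        D[b] = 1 if v["allele"] == 0 else 0
        col = v["allele"] * r + seg_of[b]
        for p in carriers[p_edge]:
            C[p, b] = seg_cn[p, col]
    C[n - 1, :n_mut] = 0     # root is mutation-free by construction

    return SimTruth(cfg=cfg, dims=dims, E=E, A=A, C=C, W=W, D=D, Q=Q, G=G,
                    segments=segments, variants=variants, events=events)


# ---------------------------------------------------------------------------
# bulk + scRNA observation models
# ---------------------------------------------------------------------------

def simulate_bulk_reads(truth: SimTruth, cfg: SimConfig, rng=None,
                        noise: bool = True) -> BulkProfile:
    """Draw mixture fractions and the (optionally noisy) bulk matrix F.

    Noise model: per sample and segment, depth ~ Poisson(depth_mean) (zero
    depths redrawn); variant read counts ~ Binomial(depth, VAF) with VAFs
    taken from the theoretical mixture copy numbers; observed fractions are
    scaled back to the segment's theoretical total copy number.  Segment
    allele columns receive the analogous BAF-based noise.
    """
    rng = np.random.default_rng(rng)
    d = truth.dims
    if truth.U is None:
        truth.U = rng.dirichlet(np.ones(d.n), size=d.m)
    F0 = truth.U @ truth.C.astype(float)
    truth.F0 = F0
    seg_of = np.argmax(truth.Q, axis=1)
    if not noise:
        F = F0.copy()
    else:
        F = np.zeros_like(F0)
        for i in range(d.m):
            depths = draw_segment_depths(d.r, cfg.depth_mean, rng)
            tot = F0[i, d.n_mut:d.n_mut + d.r] + F0[i, d.n_mut + d.r:]
            for s in range(d.r):
                dep = int(depths[s])
                if tot[s] <= 0:
                    continue
                baf = F0[i, d.n_mut + s] / tot[s]
                ar = rng.binomial(dep, np.clip(baf, 0, 1))
                F[i, d.n_mut + s] = ar / dep * tot[s]
                F[i, d.n_mut + d.r + s] = tot[s] - F[i, d.n_mut + s]
            for b in range(d.n_mut):
                s = seg_of[b]
                if tot[s] <= 0:
                    continue
                vaf = np.clip(F0[i, b] / tot[s], 0, 1)
                vr = rng.binomial(int(depths[s]), vaf)
                F[i, b] = vr / depths[s] * tot[s]
    sample_ids = [f"sample_{i}" for i in range(d.m)]
    return BulkProfile(F=F, Q=truth.Q, G=truth.G, l=d.l, g=d.g, r=d.r,
                       variant_ids=truth.variants, sample_ids=sample_ids)


def simulate_scrna(truth: SimTruth, cfg: SimConfig, rng=None,
                   noise: bool = True) -> RnaCloneProfile:
    """Allele-specific scRNA segment profiles from per-gene transcript draws.

    For each clone and segment, the number of profiled genes is uniform in
    [3, 6]; each gene's allele draws Poisson(transcript_mean * cn / 2)
    transcripts.  Averaging per allele and dividing by transcript_mean / 2
    anchors the diploid state at copy number 1 per allele; rounding gives the
    integer profile an scRNA CNA caller would report.
    """
    rng = np.random.default_rng(rng)
    d = truth.dims
    seg_truth = truth.C[:, d.n_mut:]
    if not noise:
        return RnaCloneProfile(C_rna=seg_truth.copy(),
                               clone_labels=[f"clone_{i}" for i in range(d.n)])
    lo, hi = cfg.genes_per_segment
    C_rna = np.zeros((d.n, 2 * d.r), dtype=int)
    for p in range(d.n):
        for s in range(d.r):
            n_genes = int(rng.integers(lo, hi + 1))
            cn = (seg_truth[p, s], seg_truth[p, d.r + s])
            t = draw_transcript_counts(n_genes, cn, cfg.transcript_mean, rng)
            est = t.mean(axis=0) / (cfg.transcript_mean / 2.0)
            C_rna[p, s] = int(np.rint(est[0]))
            C_rna[p, d.r + s] = int(np.rint(est[1]))
    return RnaCloneProfile(C_rna=C_rna,
                           clone_labels=[f"clone_{i}" for i in range(d.n)])


def simulate_instance(cfg: SimConfig, noise: bool = True):
    """Full instance: returns ``(BulkProfile, RnaCloneProfile, SimTruth)``."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_tree_and_genotypes(cfg, rng)
    bulk = simulate_bulk_reads(truth, cfg, rng, noise=noise)
    rna = simulate_scrna(truth, cfg, rng, noise=noise)
    return bulk, rna, truth
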