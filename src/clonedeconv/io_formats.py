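"""On-disk formats: per-sample VCFs, segment/CN tables, solution bundles.

Bulk variants travel as VCF 4.2 (one file per sample): SNVs as ordinary
records and SV breakpoint ends as BND records paired through MATEID.  The
per-sample average copy number rides in the ``CNAVG`` INFO field.  Segment
allele-specific copy numbers use a long-format TSV (sample, chrom, start,
end, cn_allele1, cn_allele2) with 1-based inclusive coordinates on disk and
half-open 0-based coordinates in memory.  scRNA clone profiles are plain
TSVs.  Solutions are written as TSV matrices plus DOT and Newick renderings
of the clonal tree and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .data_model import BulkProfile, RnaCloneProfile, Solution, ValidationError
from .simulator import SimConfig, SimTruth
from .ilp_core import ancestry_closure

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# bulk VCF + segment table
# ---------------------------------------------------------------------------

def _vcf_header(contigs: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "CNAVG"), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description", "Average copy number of the variant in this sample")])
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Structural variant type")])
    header.add_meta("INFO", items=[("ID", "MATEID"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "ID of the mate breakend")])
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    return header


def write_bulk(bulk: BulkProfile, outdir, segments: Sequence[tuple],
               contigs: Optional[dict] = None) -> dict:
    """Write per-sample VCFs and the segment CN table; returns written paths.

    ``segments`` is the ordered list of (chrom, start, end) half-open
    intervals matching the segment columns of F.  ``variant_ids`` metadata
    (chrom/pos/mates) must be present on the profile.
    """
    if bulk.variant_ids is None:
        raise ValidationError("write_bulk requires variant metadata")
    os.makedirs(outdir, exist_ok=True)
    if contigs is None:
        contigs = {}
        for chrom, _s, end in segments:
            contigs[chrom] = max(contigs.get(chrom, 0), end)
        for v in bulk.variant_ids:
            contigs[v["chrom"]] = max(contigs.get(v["chrom"], 0), v["pos"] + 2)
    sample_ids = bulk.sample_ids or [f"sample_{i}" for i in range(bulk.m)]
    paths = {"vcfs": [], "segments": os.path.join(outdir, "segments.tsv")}
    for i, sid in enumerate(sample_ids):
        path = os.path.join(outdir, f"{sid}.vcf")
        vcf = pysam.VariantFile(path, "w", header=_vcf_header(contigs))
        for b, v in enumerate(bulk.variant_ids):
            if v["kind"] == "breakpoint":
                rec = vcf.new_record(
                    contig=v["chrom"], start=v["pos"],
                    alleles=("N", f"N]{v['mate_chrom']}:{v['mate_pos'] + 1}]"),
                    id=f"bnd_{b}")
                rec.info["SVTYPE"] = "BND"
                mate = b + 1 if b % 2 == 0 else b - 1
                rec.info["MATEID"] = f"bnd_{mate}"
            else:
                rec = vcf.new_record(contig=v["chrom"], start=v["pos"],
                                     alleles=("N", "A"), id=f"snv_{b}")
            rec.info["CNAVG"] = float(bulk.F[i, b])
            rec.stop = v["pos"] + 1
            vcf.write(rec)
        vcf.close()
        paths["vcfs"].append(path)
    rows = []
    n_mut = bulk.l + bulk.g
    for i, sid in enumerate(sample_ids):
        for s, (chrom, start, end) in enumerate(segments):
            rows.append({"sample": sid, "chrom": chrom,
                         "start": start + 1, "end": end,
                         "cn_allele1": bulk.F[i, n_mut + s],
                         "cn_allele2": bulk.F[i, n_mut + bulk.r + s]})
    pd.DataFrame(rows).to_csv(paths["segments"], sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    return paths


def read_bulk_vcf(paths: Sequence[str], segment_table: str, *,
                  sv_cap: Optional[int] = None, snv_cap: Optional[int] = None,
                  seed: int = 0) -> BulkProfile:
    """Assemble a BulkProfile from per-sample VCFs plus the segment table.

    Variants falling outside every segment are dropped (count logged).
    Optional subsampling keeps the highest-support (largest mean CNAVG)
    breakpoint pairs / SNVs, with seeded random tie-breaking.
    """
    seg_df = pd.read_csv(segment_table, sep="\t")
    samples = list(dict.fromkeys(seg_df["sample"]))
    first = seg_df[seg_df["sample"] == samples[0]]
    segments = [(row.chrom, int(row.start) - 1, int(row.end))
                for row in first.itertuples()]
    r = len(segments)

    per_sample = []
    for path in paths:
        vcf = pysam.VariantFile(path)
        recs = []
        for rec in vcf:
            kind = "breakpoint" if rec.info.get("SVTYPE") == "BND" else "snv"
            recs.append({"id": rec.id, "kind": kind, "chrom": rec.contig,
                         "pos": rec.start, "cn": float(rec.info["CNAVG"]),
                         "mateid": rec.info.get("MATEID"),
                         "alt": rec.alts[0] if rec.alts else None})
        per_sample.append(recs)
    ids0 = [x["id"] for x in per_sample[0]]
    for recs in per_sample[1:]:
        if [x["id"] for x in recs] != ids0:
            raise ValidationError("sample VCFs disagree on the variant set")
    if len(per_sample) != len(samples):
        raise ValidationError("segment table samples do not match the VCF list")

    def seg_of(chrom, pos):
        for s, (c, s0, s1) in enumerate(segments):
            if c == chrom and s0 <= pos < s1:
                return s
        return None

    base = per_sample[0]
    keep, dropped = [], 0
    for j, v in enumerate(base):
        if seg_of(v["chrom"], v["pos"]) is None:
            dropped += 1
        else:
            keep.append(j)
    # a breakpoint whose mate was dropped becomes unpaired: drop the pair
    by_id = {base[j]["id"]: j for j in keep}
    keep2 = []
    for j in keep:
        v = base[j]
        if v["kind"] == "breakpoint" and v["mateid"] not in by_id:
            dropped += 1
            continue
        keep2.append(j)
    if dropped:
        logger.info("dropped %d variants outside all segments (or unpaired)", dropped)

    bnd_idx = [j for j in keep2 if base[j]["kind"] == "breakpoint"]
    snv_idx = [j for j in keep2 if base[j]["kind"] == "snv"]
    for j in bnd_idx:
        if base[j]["mateid"] is None:
            raise ValidationError(f"BND record {base[j]['id']} lacks MATEID")
    id_to_col = {base[j]["id"]: j for j in bnd_idx}
    for j in bnd_idx:
        if base[j]["mateid"] not in id_to_col:
            raise ValidationError(f"unmatched MATEID for {base[j]['id']}")

    # pair list in encounter order
    pairs, seen = [], set()
    for j in bnd_idx:
        if j in seen:
            continue
        mate = id_to_col[base[j]["mateid"]]
        pairs.append((j, mate))
        seen.update((j, mate))

    rng = np.random.default_rng(seed)
    mean_cn = {j: float(np.mean([recs[j]["cn"] for recs in per_sample]))
               for j in keep2}
    if sv_cap is not None and 2 * len(pairs) > sv_cap:
        n_keep = sv_cap // 2
        support = np.array([mean_cn[a] + mean_cn[b] for a, b in pairs])
        order = np.lexsort((rng.random(len(pairs)), -support))
        pairs = [pairs[t] for t in sorted(order[:n_keep])]
    if snv_cap is not None and len(snv_idx) > snv_cap:
        support = np.array([mean_cn[j] for j in snv_idx])
        order = np.lexsort((rng.random(len(snv_idx)), -support))
        snv_idx = [snv_idx[t] for t in sorted(order[:snv_cap])]

    bnd_cols = [j for pair in pairs for j in pair]
    l, g = len(bnd_cols), len(snv_idx)
    m = len(per_sample)
    F = np.zeros((m, l + g + 2 * r))
    variant_ids = []
    Q = np.zeros((l + g, r), dtype=int)
    for col, j in enumerate(bnd_cols + snv_idx):
        v = base[j]
        for i in range(m):
            F[i, col] = per_sample[i][j]["cn"]
        Q[col, seg_of(v["chrom"], v["pos"])] = 1
        variant_ids.append({"kind": v["kind"], "chrom": v["chrom"],
                            "pos": v["pos"], "id": v["id"]})
    G = np.zeros((l, l), dtype=int)
    for k in range(l // 2):
        G[2 * k, 2 * k + 1] = G[2 * k + 1, 2 * k] = 1
    n_mut = l + g
    for i, sid in enumerate(samples):
        sub = seg_df[seg_df["sample"] == sid]
        F[i, n_mut:n_mut + r] = sub["cn_allele1"].to_numpy()
        F[i, n_mut + r:] = sub["cn_allele2"].to_numpy()
    bulk = BulkProfile(F=F, Q=Q, G=G, l=l, g=g, r=r,
                       variant_ids=variant_ids, sample_ids=samples)
    bulk.validate()
    return bulk


# ---------------------------------------------------------------------------
# scRNA clone profile TSV
# ---------------------------------------------------------------------------

def write_rna_cna(rna: RnaCloneProfile, path) -> None:
    n, two_r = rna.C_rna.shape
    r = two_r // 2
    cols = [f"seg{s}_a1" for s in range(r)] + [f"seg{s}_a2" for s in range(r)]
    labels = rna.clone_labels or [f"clone_{i}" for i in range(n)]
    df = pd.DataFrame(rna.C_rna, columns=cols)
    df.insert(0, "clone", labels)
    df.to_csv(path, sep="\t", index=False)


def read_rna_cna(path) -> RnaCloneProfile:
    """Read a clone x 2r allele-CN TSV; non-integer entries are rounded."""
    df = pd.read_csv(path, sep="\t")
    if "clone" not in df.columns:
        raise ValidationError("RNA CNA table must have a 'clone' label column")
    if df["clone"].isna().any():
        raise ValidationError("missing clone label in RNA CNA table")
    mat = df.drop(columns=["clone"]).to_numpy(dtype=float)
    if mat.shape[1] % 2 != 0:
        raise ValidationError("RNA CNA table must have 2r allele columns")
    rounded = np.rint(mat)
    if not np.allclose(mat, rounded):
        logger.warning("non-integer scRNA copy numbers rounded to integers")
    rna = RnaCloneProfile(C_rna=rounded.astype(int),
                          clone_labels=list(df["clone"]))
    rna.validate()
    return rna


# ---------------------------------------------------------------------------
# trees and solutions
# ---------------------------------------------------------------------------

def clone_labels(n: int) -> list:
    labels = [f"clone_{i}" for i in range(n)]
    labels[n - 1] = "normal"
    return labels


def newick_string(E: np.ndarray, labels: Optional[Sequence[str]] = None) -> str:
    """Rooted Newick with internal labels; root is the normal clone."""
    n = E.shape[0]
    labels = list(labels) if labels is not None else clone_labels(n)

    def render(v: int) -> str:
        children = np.nonzero(E[v])[0]
        if len(children) == 0:
            return labels[v]
        return "(" + ",".join(render(int(c)) for c in children) + ")" + labels[v]

    return render(n - 1) + ";"


def dot_string(E: np.ndarray, labels: Optional[Sequence[str]] = None) -> str:
    n = E.shape[0]
    labels = list(labels) if labels is not None else clone_labels(n)
    lines = ["digraph clonal_tree {"]
    for i in range(n):
        lines.append(f'  n{i} [label="{labels[i]}"];')
    for i, j in zip(*np.nonzero(E)):
        lines.append(f"  n{i} -> n{j};")
    lines.append("}")
    return "\n".join(lines)


def write_solution(sol: Solution, outdir, manifest: Optional[dict] = None) -> dict:
    """Emit U/C/M TSVs, tree renderings, per-edge mutation lists, manifest."""
    os.makedirs(outdir, exist_ok=True)
    n = sol.C.shape[0]
    paths = {}

    def save(name, arr, fmt):
        p = os.path.join(outdir, name)
        np.savetxt(p, arr, delimiter="\t", fmt=fmt)
        paths[name] = p

    save("U.tsv", sol.U, _FLOAT_FMT)
    save("C.tsv", sol.C, "%d")
    save("M.tsv", sol.M, "%d")
    save("E.tsv", sol.E, "%d")
    labels = clone_labels(n)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(newick_string(sol.E, labels) + "\n")
    with open(os.path.join(outdir, "tree.dot"), "w") as fh:
        fh.write(dot_string(sol.E, labels) + "\n")
    rows = []
    n_mut = sol.W.shape[2]
    for k in range(n_mut):
        where = np.argwhere(sol.W[:, :, k] == 1)
        for i, j in where:
            rows.append({"parent": labels[i], "child": labels[j],
                         "mutation": k, "allele": int(sol.D[k])})
    pd.DataFrame(rows, columns=["parent", "child", "mutation", "allele"]).to_csv(
        os.path.join(outdir, "edge_mutations.tsv"), sep="\t", index=False)
    manifest = dict(manifest or {})
    manifest.setdefault("objective", sol.objective)
    manifest.setdefault("term_breakdown", sol.term_breakdown)
    manifest.setdefault("solver_gap", sol.gap)
    manifest.setdefault("timed_out", sol.timed_out)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest.json"] = os.path.join(outdir, "manifest.json")
    return paths


def read_solution_matrices(outdir) -> dict:
    out = {}
    for name, dtype in (("U.tsv", float), ("C.tsv", int), ("M.tsv", int),
                        ("E.tsv", int)):
        out[name[:-4]] = np.loadtxt(os.path.join(outdir, name),
                                    delimiter="\t", dtype=dtype, ndmin=2)
    return out


# ---------------------------------------------------------------------------
# simulator truth bundle
# ---------------------------------------------------------------------------

def write_truth_bundle(truth: SimTruth, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    np.savetxt(os.path.join(outdir, "truth_C.tsv"), truth.C, "%d", delimiter="\t")
    np.savetxt(os.path.join(outdir, "truth_U.tsv"), truth.U, _FLOAT_FMT, delimiter="\t")
    np.savetxt(os.path.join(outdir, "truth_E.tsv"), truth.E, "%d", delimiter="\t")
    with open(os.path.join(outdir, "truth_tree.nwk"), "w") as fh:
        fh.write(newick_string(truth.E) + "\n")
    cfg = truth.cfg
    meta = {"n": cfg.n, "m": cfg.m, "g": cfg.g, "n_svs": cfg.n_svs, "r": cfg.r,
            "seed": cfg.seed, "depth_mean": cfg.depth_mean,
            "sv_length_mean": cfg.sv_length_mean,
            "transcript_mean": cfg.transcript_mean}
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_truth_bundle(outdir) -> SimTruth:
    with open(os.path.join(outdir, "sim_config.json")) as fh:
        meta = json.load(fh)
    cfg = SimConfig(n=meta["n"], m=meta["m"], g=meta["g"],
                    n_svs=meta["n_svs"], r=meta["r"], seed=meta["seed"])
    C = np.loadtxt(os.path.join(outdir, "truth_C.tsv"), dtype=int,
                   delimiter="\t", ndmin=2)
    U = np.loadtxt(os.path.join(outdir, "truth_U.tsv"), dtype=float,
                   delimiter="\t", ndmin=2)
    E = np.loadtxt(os.path.join(outdir, "truth_E.tsv"), dtype=int,
                   delimiter="\t", ndmin=2)
    from .data_model import ProblemDims
    dims = ProblemDims(n=cfg.n, m=U.shape[0], l=cfg.l, g=cfg.g, r=cfg.r)
    return SimTruth(cfg=cfg, dims=dims, E=E, A=ancestry_closure(E), C=C, U=U)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
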