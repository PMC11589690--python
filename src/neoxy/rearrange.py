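"""Whole-genome alignment block filtering, variant counting and
rearrangement classification.

Blocks are filtered by identity and length, SNPs and indel events are tallied
from gapped per-block sequence pairs, and each block is classified as
syntenic, inversion, translocation or duplication by a simple
order/orientation/copy scheme:

* duplication — the block's query interval largely re-uses another block's
  query interval (two reference copies of one query segment);
* inversion — reverse-strand alignment between corresponding chromosomes;
* syntenic — member of the longest collinear chain (longest strictly
  increasing subsequence of query positions along the reference);
* translocation — everything else (wrong chromosome or out of order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AlignmentBlock


def filter_blocks(
    blocks: list[AlignmentBlock],
    min_identity: float = 95.0,
    min_length: int = 2000,
) -> list[AlignmentBlock]:
    """Keep blocks with identity >= ``min_identity`` and reference length
    >= ``min_length`` (idempotent)."""
    return [
        b for b in blocks
        if b.identity >= min_identity and b.ref_length >= min_length
    ]


# ---------------------------------------------------------------------------
# per-block variant counting
# ---------------------------------------------------------------------------

@dataclass
class VariantCounts:
    per_block: pd.DataFrame  # block, snps, indels
    total_snps: int
    total_indels: int
    median_snps_per_mb: float
    median_indels_per_mb: float


def count_block_variants(
    seq_pairs: list[tuple[str, str]],
    blocks: list[AlignmentBlock] | None = None,
    mb: int = 1_000_000,
) -> VariantCounts:
    """Count SNPs (mismatching non-gap columns) and indel events (maximal gap
    runs in either sequence) per aligned block pair.

    Per-Mb medians are computed over the 1 Mb reference bins intersecting the
    blocks when ``blocks`` (parallel to ``seq_pairs``) are provided.
    """
    rows = []
    bin_snps: dict[tuple[str, int], int] = {}
    bin_indels: dict[tuple[str, int], int] = {}
    for bi, (ref_s, qry_s) in enumerate(seq_pairs):
        if len(ref_s) != len(qry_s):
            raise ValueError(f"block {bi}: aligned sequences differ in length")
        ra = np.frombuffer(ref_s.encode(), dtype=np.uint8)
        qa = np.frombuffer(qry_s.encode(), dtype=np.uint8)
        gap = ord("-")
        r_gap = ra == gap
        q_gap = qa == gap
        snp_cols = (~r_gap) & (~q_gap) & (ra != qa)
        any_gap = r_gap | q_gap
        # maximal gap runs count once each
        run_starts = any_gap & ~np.concatenate(([False], any_gap[:-1]))
        n_snps = int(snp_cols.sum())
        n_indels = int(run_starts.sum())
        rows.append({"block": bi, "snps": n_snps, "indels": n_indels})
        if blocks is not None:
            b = blocks[bi]
            ref_offset = np.cumsum(~r_gap) - 1 + b.ref_start
            for pos in ref_offset[snp_cols]:
                key = (b.ref_chrom, int(pos) // mb)
                bin_snps[key] = bin_snps.get(key, 0) + 1
                bin_indels.setdefault(key, 0)
            for pos in ref_offset[run_starts]:
                key = (b.ref_chrom, int(pos) // mb)
                bin_indels[key] = bin_indels.get(key, 0) + 1
                bin_snps.setdefault(key, 0)
            # bins intersected by the block but with no events still count
            for mbin in range(b.ref_start // mb, (b.ref_end - 1) // mb + 1):
                bin_snps.setdefault((b.ref_chrom, mbin), 0)
                bin_indels.setdefault((b.ref_chrom, mbin), 0)
    per_block = pd.DataFrame(rows, columns=["block", "snps", "indels"])
    med_snp = float(np.median(list(bin_snps.values()))) if bin_snps else float("nan")
    med_ind = float(np.median(list(bin_indels.values()))) if bin_indels else float("nan")
    return VariantCounts(
        per_block=per_block,
        total_snps=int(per_block["snps"].sum()),
        total_indels=int(per_block["indels"].sum()),
        median_snps_per_mb=med_snp,
        median_indels_per_mb=med_ind,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _chrom_correspondence(blocks: list[AlignmentBlock]) -> dict[str, str]:
    """Reference chromosome -> query chromosome carrying most aligned bases."""
    tally: dict[str, dict[str, int]] = {}
    for b in blocks:
        tally.setdefault(b.ref_chrom, {}).setdefault(b.query_chrom, 0)
        tally[b.ref_chrom][b.query_chrom] += b.ref_length
    return {rc: max(qc, key=lambda q: (qc[q], q)) for rc, qc in tally.items()}


def _lis_members(order_values: list[float]) -> set[int]:
    """Indices belonging to one longest strictly increasing subsequence
    (deterministic: among ties the earliest predecessor is chosen)."""
    n = len(order_values)
    if n == 0:
        return set()
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if order_values[j] < order_values[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = int(np.argmax(best))
    members = set()
    while end != -1:
        members.add(end)
        end = prev[end]
    return members


def classify_blocks(
    blocks: list[AlignmentBlock],
    duplication_overlap: float = 0.5,
) -> tuple[list[AlignmentBlock], pd.DataFrame]:
    """Classify blocks and summarize counts and mean sizes per class.

    Classification is content-based (input order does not matter): blocks are
    canonically sorted internally, the collinear chain is found per reference
    chromosome by longest increasing subsequence over query positions of
    forward-strand blocks on the corresponding query chromosome, and the
    rules are applied in priority order duplication > inversion > syntenic >
    translocation. Of two blocks sharing a query interval, the one outside
    the collinear chain is the duplication.
    """
    order = sorted(
        range(len(blocks)),
        key=lambda i: (blocks[i].ref_chrom, blocks[i].ref_start,
                       blocks[i].query_chrom, blocks[i].query_start),
    )
    sblocks = [blocks[i] for i in order]
    corr = _chrom_correspondence(sblocks)

    # collinear chain per reference chromosome
    in_chain: dict[int, bool] = {i: False for i in range(len(sblocks))}
    by_ref: dict[str, list[int]] = {}
    for i, b in enumerate(sblocks):
        by_ref.setdefault(b.ref_chrom, []).append(i)
    for rc, idxs in by_ref.items():
        cand = [i for i in idxs
                if sblocks[i].strand == "+" and sblocks[i].query_chrom == corr[rc]]
        members = _lis_members([sblocks[i].query_start for i in cand])
        for k in members:
            in_chain[cand[k]] = True

    # duplication: query interval overlapping >= duplication_overlap of
    # another block's query interval
    dup: set[int] = set()
    for i in range(len(sblocks)):
        for j in range(len(sblocks)):
            if i == j:
                continue
            a, b = sblocks[i], sblocks[j]
            if a.query_chrom != b.query_chrom:
                continue
            ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
            if ov <= 0 or ov < duplication_overlap * b.query_length:
                continue
            if in_chain[i] and not in_chain[j]:
                dup.add(j)
            elif in_chain[j] and not in_chain[i]:
                dup.add(i)
            elif not in_chain[i] and not in_chain[j]:
                # neither is collinear: call the later (by reference start,
                # then shorter) copy the duplication
                key_i = (a.ref_start, -a.ref_length, a.ref_chrom)
                key_j = (b.ref_start, -b.ref_length, b.ref_chrom)
                dup.add(i if key_i > key_j else j)

    labels: list[str] = []
    for i, b in enumerate(sblocks):
        if i in dup:
            labels.append("duplication")
        elif b.strand == "-" and b.query_chrom == corr[b.ref_chrom]:
            labels.append("inversion")
        elif in_chain[i]:
            labels.append("syntenic")
        else:
            labels.append("translocation")

    out = [replace(blocks[oi], classification=labels[k])
           for k, oi in enumerate(order)]
    # restore input order
    restored: list[AlignmentBlock] = [None] * len(blocks)  # type: ignore
    for k, oi in enumerate(order):
        restored[oi] = out[k]
    summary = (
        pd.DataFrame({
            "classification": [b.classification for b in restored],
            "size": [b.ref_length for b in restored],
        })
        .groupby("classification")
        .agg(count=("size", "size"), mean_size=("size", "mean"))
        .reset_index()
    )
    return restored, summary
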