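"""Gametolog separation inside candidate heterogametic regions.

Within a region where males carry diverged X and Y haplotypes, the two
phased haplotypes of every male fall into two clusters: the Y haplotypes of
all males form one tight cluster (they share the fixed X-Y differences) and
everything else — male X haplotypes and all female haplotypes — forms the
other. The module filters variants with a freebayes-style hard-filter
cascade, clusters phased haplotypes, assigns each male's Y haplotype,
regenotypes the region to haploid X and Y panels, and extracts per-gene
gametolog coding sequences.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import GeneModel, GenomicInterval, Genotype, VariantRecord
from .scan import SexLinkedRegion

RULE_TAGS = {
    1: "low_qual_or_site_depth",
    2: "het_low_depth",
    3: "hom_low_qual_depth",
    4: "het_qual_below_depth_factor",
    5: "depth_spike",
    6: "repeat_overlap",
}


@dataclass(frozen=True)
class FilterParams:
    """Hard-filter cascade thresholds for freebayes-style variant calls."""

    min_site_qual: float = 30.0
    min_depth: int = 3
    min_het_depth: int = 4
    min_hom_qual: float = 50.0
    min_hom_depth: int = 4
    het_qual_depth_factor: float = 2.0
    max_depth_sd_factor: float = 3.0
    repeat_mask: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for v in (self.min_site_qual, self.min_depth, self.min_het_depth,
                  self.min_hom_qual, self.min_hom_depth,
                  self.het_qual_depth_factor, self.max_depth_sd_factor):
            if v < 0:
                raise ValueError("filter thresholds must be >= 0")


def _site_depth(rec: VariantRecord) -> int | None:
    ds = [d for d in rec.depths if d is not None]
    return sum(ds) if ds else None


def _early_rule(rec: VariantRecord, p: FilterParams) -> int | None:
    """Rules 1-3, which do not depend on the dataset-wide mean depth."""
    sd = _site_depth(rec)
    if rec.qual < p.min_site_qual or (sd is not None and sd < p.min_depth):
        return 1
    for g, dp in zip(rec.genotypes, rec.depths):
        if g.is_het and dp is not None and dp < p.min_het_depth:
            return 2
    for g, dp in zip(rec.genotypes, rec.depths):
        if (g.is_hom and rec.qual < p.min_hom_qual
                and dp is not None and dp < p.min_hom_depth):
            return 3
    return None


def filter_variants(
    records: list[VariantRecord], params: FilterParams = FilterParams()
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the six-rule hard-filter cascade.

    A record is removed iff it violates at least one rule and is tagged with
    the first violated rule. The "average depth" of rules 4-5 is the mean of
    all non-missing genotype depths over records surviving rules 1-3, so the
    result does not depend on input order. Returns ``(kept, removed)`` with
    removed entries tagged by rule name.
    """
    if all(d is None for rec in records for d in rec.depths):
        raise ValueError("no DP field in any record: depth filters undefined")

    early: list[int | None] = [_early_rule(r, params) for r in records]
    depth_sum = 0
    depth_n = 0
    for rec, rule in zip(records, early):
        if rule is None:
            for d in rec.depths:
                if d is not None:
                    depth_sum += d
                    depth_n += 1
    mean_depth = depth_sum / depth_n if depth_n else 0.0
    depth_cap = mean_depth + params.max_depth_sd_factor * np.sqrt(mean_depth)

    mask_starts: dict[str, list[int]] = {}
    mask_ends: dict[str, list[int]] = {}
    for iv in sorted(params.repeat_mask, key=lambda i: (i.chrom, i.start)):
        mask_starts.setdefault(iv.chrom, []).append(iv.start)
        mask_ends.setdefault(iv.chrom, []).append(iv.end)

    def in_repeat(rec: VariantRecord) -> bool:
        starts = mask_starts.get(rec.chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, rec.end - 1)
        # any masked interval starting before rec.end may overlap
        for j in range(i - 1, -1, -1):
            if mask_ends[rec.chrom][j] > rec.start:
                return True
            # intervals are sorted by start; an interval further left can
            # still overlap only if it extends past rec.start
        return False

    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec, rule in zip(records, early):
        if rule is None:
            if any(g.is_het for g in rec.genotypes) and \
                    rec.qual < params.het_qual_depth_factor * mean_depth:
                rule = 4
            elif (md := rec.max_depth()) is not None and md > depth_cap:
                rule = 5
            elif in_repeat(rec):
                rule = 6
        if rule is None:
            kept.append(rec)
        else:
            removed.append((rec, RULE_TAGS[rule]))
    return kept, removed


# ---------------------------------------------------------------------------
# haplotype clustering
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased haplotypes over the filtered sites of one region.

    ``alleles`` has one row per (sample, haplotype-index) pair in the order
    of ``labels``; missing alleles are encoded as -1.
    """

    region: GenomicInterval
    positions: np.ndarray
    alleles: np.ndarray  # (2 * n_samples, n_sites), int8, -1 = missing
    labels: list[tuple[str, int]]  # (sample, haplotype index 0/1)
    sexes: dict[str, str]


def build_haplotype_matrix(
    records: list[VariantRecord],
    samples: list[str],
    sexes: dict[str, str],
    region: GenomicInterval,
) -> HaplotypeMatrix:
    """Collect phased haplotype alleles at the region's variant sites.

    A heterozygous unphased male genotype inside the region is an error: the
    clustering stage is meaningless without phase.
    """
    in_region = [r for r in records
                 if r.chrom == region.chrom and region.start <= r.start < region.end]
    positions = np.array([r.start for r in in_region], dtype=np.int64)
    n_haps = 2 * len(samples)
    alleles = np.full((n_haps, len(positions)), -1, dtype=np.int8)
    for j, rec in enumerate(in_region):
        for si, sample in enumerate(samples):
            g = rec.genotypes[si]
            if len(g.alleles) != 2:
                continue
            a, b = g.alleles
            if g.is_het and not g.phased and sexes.get(sample) == "M":
                raise ValueError(
                    f"unphased heterozygous male genotype for {sample} at "
                    f"{rec.chrom}:{rec.start}; phase the input first"
                )
            if a is not None:
                alleles[2 * si, j] = a
            if b is not None:
                alleles[2 * si + 1, j] = b
    labels = [(s, h) for s in samples for h in (0, 1)]
    return HaplotypeMatrix(region, positions, alleles, labels, dict(sexes))


@dataclass
class GametologAssignment:
    """Result of Y/X haplotype clustering in one region."""

    region: GenomicInterval
    status: str  # assigned | ambiguous | rejected
    y_haplotype: dict[str, int] = field(default_factory=dict)  # male -> hap index
    separation: float = float("nan")
    n_sites: int = 0


def _pairwise_mismatch(alleles: np.ndarray, min_sites: int) -> np.ndarray:
    n = alleles.shape[0]
    dist = np.full((n, n), np.nan)
    valid = alleles >= 0
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_both = int(both.sum())
            if n_both < min_sites:
                continue
            d = float((alleles[i, both] != alleles[j, both]).mean())
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_haplotypes(
    matrix: HaplotypeMatrix, min_sites: int = 20, min_separation: float = 3.0
) -> GametologAssignment:
    """Average-linkage clustering of phased haplotypes into two clusters.

    Distances are mismatch fractions over co-called sites (pairs with fewer
    than ``min_sites`` shared sites get the mean defined distance). The
    region is ``assigned`` when one cluster contains exactly one haplotype of
    every male and no female haplotype — the Y cluster — and the
    between/within separation ratio reaches ``min_separation``.
    """
    n_sites = len(matrix.positions)
    if n_sites < min_sites:
        return GametologAssignment(matrix.region, "rejected", n_sites=n_sites)
    dist = _pairwise_mismatch(matrix.alleles, min_sites)
    off = dist[np.triu_indices_from(dist, k=1)]
    defined = off[np.isfinite(off)]
    if len(defined) == 0:
        return GametologAssignment(matrix.region, "rejected", n_sites=n_sites)
    if np.all(defined == 0):
        return GametologAssignment(matrix.region, "rejected", n_sites=n_sites)
    filled = dist.copy()
    filled[~np.isfinite(filled)] = float(defined.mean())
    condensed = squareform(filled, checks=False)
    tree = linkage(condensed, method="average")
    assign = fcluster(tree, t=2, criterion="maxclust")

    males = [s for s, sex in matrix.sexes.items() if sex == "M"]
    clusters = {c: [matrix.labels[i] for i in np.nonzero(assign == c)[0]]
                for c in (1, 2)}
    y_cluster = None
    for c, members in clusters.items():
        by_sample: dict[str, int] = {}
        for sample, _h in members:
            by_sample[sample] = by_sample.get(sample, 0) + 1
        if (set(by_sample) == set(males)
                and all(v == 1 for v in by_sample.values())):
            y_cluster = c
            break

    within = []
    between = []
    for i in range(len(matrix.labels)):
        for j in range(i + 1, len(matrix.labels)):
            d = filled[i, j]
            (within if assign[i] == assign[j] else between).append(d)
    mean_within = float(np.mean(within)) if within else 0.0
    mean_between = float(np.mean(between)) if between else 0.0
    separation = (mean_between / mean_within) if mean_within > 0 else float("inf")

    if y_cluster is None:
        return GametologAssignment(matrix.region, "ambiguous",
                                   separation=separation, n_sites=n_sites)
    if separation < min_separation:
        return GametologAssignment(matrix.region, "rejected",
                                   separation=separation, n_sites=n_sites)
    y_hap = {}
    for sample, h in clusters[y_cluster]:
        y_hap[sample] = h
    return GametologAssignment(matrix.region, "assigned", y_hap, separation, n_sites)


# ---------------------------------------------------------------------------
# haploid regenotyping
# ---------------------------------------------------------------------------

@dataclass
class HaploidPanel:
    """Haploid calls: one allele per (panel sample, site)."""

    samples: list[str]
    records: list[VariantRecord]


def regenotype_haploid(
    assignment: GametologAssignment,
    records: list[VariantRecord],
    samples: list[str],
    sexes: dict[str, str],
) -> tuple[HaploidPanel, HaploidPanel]:
    """Split diploid calls in the assigned region into haploid X and Y panels.

    Each male contributes his X-assigned haplotype to the X panel and his
    Y-assigned haplotype to the Y panel; females contribute both haplotypes
    to the X panel. Missing alleles stay missing.
    """
    if assignment.status != "assigned":
        raise ValueError(f"region not assigned (status={assignment.status})")
    region = assignment.region
    males = [s for s in samples if sexes.get(s) == "M"]
    females = [s for s in samples if sexes.get(s) == "F"]
    x_samples = [f"{m}_X" for m in males] + [f"{f}_h{h + 1}"
                                             for f in females for h in (0, 1)]
    y_samples = [f"{m}_Y" for m in males]
    x_records: list[VariantRecord] = []
    y_records: list[VariantRecord] = []
    s_index = {s: i for i, s in enumerate(samples)}
    for rec in records:
        if rec.chrom != region.chrom or not (region.start <= rec.start < region.end):
            continue
        x_gts: list[Genotype] = []
        x_dp: list[int | None] = []
        x_gq: list[int | None] = []
        y_gts: list[Genotype] = []
        y_dp: list[int | None] = []
        y_gq: list[int | None] = []
        for m in males:
            i = s_index[m]
            g = rec.genotypes[i]
            y_idx = assignment.y_haplotype[m]
            if len(g.alleles) == 2:
                x_gts.append(Genotype((g.alleles[1 - y_idx],)))
                y_gts.append(Genotype((g.alleles[y_idx],)))
            else:
                x_gts.append(Genotype((None,)))
                y_gts.append(Genotype((None,)))
            x_dp.append(rec.depths[i])
            x_gq.append(rec.gqs[i])
            y_dp.append(rec.depths[i])
            y_gq.append(rec.gqs[i])
        for f in females:
            i = s_index[f]
            g = rec.genotypes[i]
            for h in (0, 1):
                a = g.alleles[h] if len(g.alleles) == 2 else None
                x_gts.append(Genotype((a,)))
                x_dp.append(rec.depths[i])
                x_gq.append(rec.gqs[i])
        x_records.append(VariantRecord(rec.chrom, rec.start, rec.ref, rec.alts,
                                       rec.qual, x_gts, x_dp, x_gq))
        y_records.append(VariantRecord(rec.chrom, rec.start, rec.ref, rec.alts,
                                       rec.qual, y_gts, y_dp, y_gq))
    return HaploidPanel(x_samples, x_records), HaploidPanel(y_samples, y_records)


# ---------------------------------------------------------------------------
# gametolog pair extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GametologPair:
    """One gene's consensus X and Y coding sequences (coding orientation)."""

    gene_id: str
    x_seq: str
    y_seq: str
    assignment: str  # sex-linked | PAR


def _consensus_alleles(panel: HaploidPanel) -> dict[tuple[str, int], tuple[str, str]]:
    """Majority allele per site; ties and all-missing fall back to REF."""
    out: dict[tuple[str, int], tuple[str, str]] = {}
    for rec in panel.records:
        counts: dict[int, int] = {}
        for g in rec.genotypes:
            a = g.alleles[0]
            if a is not None:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        best = max(counts, key=lambda a: (counts[a], a == 0, -a))
        if best == 0:
            continue  # reference allele: no edit needed
        allele = rec.alts[best - 1]
        out[(rec.chrom, rec.start)] = (rec.ref, allele)
    return out


def _apply_alleles(segment: str, seg_start: int,
                   edits: list[tuple[int, str, str]]) -> str:
    """Apply (pos, ref, alt) edits to a genomic segment; positions absolute."""
    seq = segment
    for pos, ref, alt in sorted(edits, reverse=True):
        off = pos - seg_start
        if off < 0 or off + len(ref) > len(seq):
            continue
        if seq[off:off + len(ref)] != ref:
            warnings.warn(f"reference mismatch at offset {off}; edit skipped")
            continue
        seq = seq[:off] + alt + seq[off + len(ref):]
    return seq


_COMP = str.maketrans("ACGTN", "TGCAN")


def extract_gametolog_pairs(
    x_panel: HaploidPanel,
    y_panel: HaploidPanel,
    reference: dict[str, str],
    genes: list[GeneModel],
    regions: list[SexLinkedRegion],
) -> list[GametologPair]:
    """Consensus X and Y CDS per gene, with sex-linked/PAR assignment.

    The consensus haploid allele (majority; ties to reference) is substituted
    into the reference CDS; indel alleles shift downstream coordinates within
    the CDS part. A gene is sex-linked iff its whole CDS span lies inside a
    heterogametic region; genes straddling a region boundary are conservatively
    assigned PAR with a warning.
    """
    x_cons = _consensus_alleles(x_panel)
    y_cons = _consensus_alleles(y_panel)
    het_regions = [r for r in regions if r.region_class == "heterogametic"]
    pairs: list[GametologPair] = []
    for gene in genes:
        span = gene.span
        inside = any(r.interval.contains(span) for r in het_regions)
        straddles = any(
            r.interval.overlaps(span) and not r.interval.contains(span)
            for r in het_regions
        )
        if straddles:
            warnings.warn(
                f"gene {gene.gene_id} straddles a region boundary; assigned PAR"
            )
        assignment = "sex-linked" if inside and not straddles else "PAR"
        seqs = {}
        for panel_name, cons in (("x", x_cons), ("y", y_cons)):
            parts = []
            for s, e in gene.cds_parts:
                edits = [
                    (pos, ref, alt)
                    for (chrom, pos), (ref, alt) in cons.items()
                    if chrom == gene.chrom and s <= pos < e
                ]
                parts.append(_apply_alleles(reference[gene.chrom][s:e], s, edits))
            seq = "".join(parts)
            if gene.strand == "-":
                seq = seq.translate(_COMP)[::-1]
            seqs[panel_name] = seq
        pairs.append(GametologPair(gene.gene_id, seqs["x"], seqs["y"], assignment))
    return pairs
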