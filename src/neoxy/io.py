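"""Readers and writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open. Conversions to the 1-based
conventions of VCF, RepeatMasker ``.out`` and MUMmer ``show-coords`` output
happen only inside this module, so the rest of the package never performs an
off-by-one adjustment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Genotype",
    "VariantRecord",
    "RepeatHit",
    "GeneModel",
    "AlignmentBlock",
    "read_bed",
    "write_bed",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_alignment_blocks",
    "write_paf",
    "write_coords_tsv",
    "read_sex_table",
    "write_sex_table",
    "read_bedgraph",
    "write_bedgraph",
]

MISSING = None


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genotype:
    """Alleles of one sample at one site; ``None`` encodes a missing allele.

    ``alleles`` has length 2 for diploid calls and 1 for haploid calls.
    ``phased`` mirrors the ``|`` separator of the VCF GT field. The
    ``is_het``/``is_hom``/``is_missing`` flags are precomputed: genotype
    objects are immutable and iterated millions of times by the windowed
    scan and the filter cascade.
    """

    __slots__ = ("alleles", "phased", "is_het", "is_hom", "is_missing")

    def __init__(self, alleles: tuple[int | None, ...], phased: bool = False):
        self.alleles = alleles
        self.phased = phased
        diploid = len(alleles) == 2
        self.is_missing = all(a is None for a in alleles)
        self.is_het = (diploid and alleles[0] is not None
                       and alleles[1] is not None and alleles[0] != alleles[1])
        self.is_hom = diploid and alleles[0] is not None and alleles[0] == alleles[1]

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Genotype)
                and self.alleles == other.alleles and self.phased == other.phased)

    def __hash__(self) -> int:
        return hash((self.alleles, self.phased))

    def __repr__(self) -> str:
        sep = "|" if self.phased else "/"
        return "Genotype(" + sep.join(
            "." if a is None else str(a) for a in self.alleles) + ")"


@dataclass(slots=True)
class VariantRecord:
    """One multi-sample variant site (SNV or indel).

    ``start`` is the 0-based position of the first REF base; the interval
    covered is ``[start, start + len(ref))``.
    """

    chrom: str
    start: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    genotypes: list[Genotype]
    depths: list[int | None]
    gqs: list[int | None]

    def validate(self) -> "VariantRecord":
        """Check allele indices and depths; called at I/O boundaries."""
        n_alleles = 1 + len(self.alts)
        for g in self.genotypes:
            for a in g.alleles:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.start}"
                    )
        for d in self.depths:
            if d is not None and d < 0:
                raise ValueError(f"negative depth at {self.chrom}:{self.start}")
        return self

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def max_depth(self) -> int | None:
        ds = [d for d in self.depths if d is not None]
        return max(ds) if ds else None


@dataclass(frozen=True, slots=True)
class RepeatHit:
    """One RepeatMasker annotation: a genomic interval assigned to a repeat
    family, with percent divergence from the family consensus."""

    interval: GenomicInterval
    family: str
    repeat_class: str
    divergence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 100.0):
            raise ValueError(f"divergence {self.divergence} outside [0, 100]")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A protein-coding gene as an ordered set of CDS parts.

    Parts are stored in ascending genomic order; for minus-strand genes the
    coding order is the reverse. ``phases`` follow the GFF3 convention.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_parts: tuple[tuple[int, int], ...]
    phases: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.cds_parts:
            if start < prev_end:
                raise ValueError(f"overlapping/unordered CDS parts in {self.gene_id}")
            if start >= end:
                raise ValueError(f"empty CDS part in {self.gene_id}")
            prev_end = end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.cds_parts[0][0], self.cds_parts[-1][1], self.strand
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced CDS in coding (5'->3') orientation."""
        seq = "".join(reference[self.chrom][s:e] for s, e in self.cds_parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(slots=True)
class AlignmentBlock:
    """One reference<->query whole-genome alignment interval."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str
    identity: float
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.ref_end <= self.ref_start or self.query_end <= self.query_start:
            raise ValueError("alignment block intervals must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED4(+strand) intervals; coordinates kept 0-based half-open."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand != ".":
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF 4.x file into ``(sample_names, records)``.

    POS is converted to a 0-based start. Phase is taken from the GT
    separator. A file without a GT FORMAT raises :class:`FormatError`.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT definition")
        samples = list(vf.header.samples)
        for rec in vf:
            genotypes: list[Genotype] = []
            depths: list[int | None] = []
            gqs: list[int | None] = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    alleles: tuple[int | None, ...] = (None,) * max(1, len(gt or (None, None)))
                    phased = False
                else:
                    alleles = tuple(gt)
                    phased = bool(call.phased)
                genotypes.append(Genotype(alleles, phased))
                dp = call.get("DP")
                depths.append(int(dp) if dp is not None else None)
                gq = call.get("GQ")
                gqs.append(int(gq) if gq is not None else None)
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    start=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    genotypes=genotypes,
                    depths=depths,
                    gqs=gqs,
                ).validate()
            )
    return samples, records


def _format_gt(g: Genotype) -> str:
    sep = "|" if g.phased else "/"
    return sep.join("." if a is None else str(a) for a in g.alleles)


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records as VCF 4.2; internal 0-based starts become 1-based POS."""
    if contigs is None:
        contigs = {}
        for rec in records:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            if len(rec.genotypes) != len(samples):
                raise ValueError(
                    f"record at {rec.chrom}:{rec.start} has {len(rec.genotypes)} "
                    f"genotypes for {len(samples)} samples"
                )
            alt = ",".join(rec.alts) if rec.alts else "."
            cols = [
                rec.chrom,
                str(rec.start + 1),
                ".",
                rec.ref,
                alt,
                f"{rec.qual:g}",
                "PASS",
                ".",
                "GT:DP:GQ",
            ]
            for g, dp, gq in zip(rec.genotypes, rec.depths, rec.gqs):
                cols.append(
                    ":".join(
                        [
                            _format_gt(g),
                            "." if dp is None else str(dp),
                            "." if gq is None else str(gq),
                        ]
                    )
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene models: gene/mRNA/CDS)
# ---------------------------------------------------------------------------

def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Collect CDS features grouped by their parent gene.

    CDS parents may be mRNAs; mRNA features are mapped back to their gene so
    each :class:`GeneModel` aggregates the CDS of one gene (first mRNA wins
    if several isoforms are present).
    """
    mrna_to_gene: dict[str, str] = {}
    gene_strand: dict[str, str] = {}
    gene_chrom: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int, int]]] = {}
    gene_of_first_mrna: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, phase, attrs = fields
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene{lineno}")
                gene_strand[gid] = strand
                gene_chrom[gid] = chrom
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid and parent:
                    mrna_to_gene[mid] = parent
                    gene_of_first_mrna.setdefault(parent, mid)
            elif ftype == "CDS":
                parent = a.get("Parent", a.get("ID", f"cds{lineno}"))
                gid = mrna_to_gene.get(parent, parent)
                if gid in gene_of_first_mrna and gene_of_first_mrna[gid] != parent:
                    continue
                gene_strand.setdefault(gid, strand)
                gene_chrom.setdefault(gid, chrom)
                ph = int(phase) if phase in ("0", "1", "2") else 0
                cds.setdefault(gid, []).append((int(start) - 1, int(end), ph))
    genes = []
    for gid, parts in cds.items():
        parts.sort()
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=gene_chrom[gid],
                strand=gene_strand[gid],
                cds_parts=tuple((s, e) for s, e, _ in parts),
                phases=tuple(p for _, _, p in parts),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.cds_parts[0][0]))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\tneoxy\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tneoxy\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            phases = g.phases or (0,) * len(g.cds_parts)
            for (s, e), ph in zip(g.cds_parts, phases):
                fh.write(
                    f"{g.chrom}\tneoxy\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query     matching"
    "  repeat          position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)    repeat"
    "  class/family    begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatHit]:
    """Parse a standard RepeatMasker ``.out`` table (3 header lines).

    Query begin (1-based) is converted to a 0-based start; a 'C' orientation
    is normalized to strand '-'.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 14:
            raise FormatError(
                f"{path}:{lineno}: expected >= 14 RepeatMasker columns, got {len(fields)}"
            )
        div = float(fields[1])
        chrom = fields[4]
        start = int(fields[5]) - 1
        end = int(fields[6])
        strand = "-" if fields[8] == "C" else "+"
        family = fields[9]
        rclass = fields[10]
        try:
            hits.append(
                RepeatHit(GenomicInterval(chrom, start, end, strand), family, rclass, div)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_repeatmasker_out(hits: Sequence[RepeatHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, start=1):
            iv = h.interval
            orient = "C" if iv.strand == "-" else "+"
            fh.write(
                f"{1000:>5} {h.divergence:5.1f}  0.0  0.0  {iv.chrom}"
                f" {iv.start + 1} {iv.end} (0) {orient} {h.family}"
                f" {h.repeat_class} 1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Alignment blocks: PAF and MUMmer show-coords TSV
# ---------------------------------------------------------------------------

def read_alignment_blocks(path: str | os.PathLike, dialect: str) -> list[AlignmentBlock]:
    """Read pairwise alignment blocks from PAF or ``show-coords -T`` TSV.

    Both dialects map onto the same :class:`AlignmentBlock`; coords-TSV
    1-based inclusive coordinates become 0-based half-open, and a reversed
    query range encodes strand '-'.
    """
    if dialect == "paf":
        return _read_paf(path)
    if dialect == "coords-tsv":
        return _read_coords_tsv(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}; use 'paf' or 'coords-tsv'")


def _read_paf(path: str | os.PathLike) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            # PAF: query first, target (reference) second; both 0-based half-open
            matches, aln_len = int(f[9]), int(f[10])
            identity = 100.0 * matches / aln_len if aln_len else 0.0
            blocks.append(
                AlignmentBlock(
                    ref_chrom=f[5],
                    ref_start=int(f[7]),
                    ref_end=int(f[8]),
                    query_chrom=f[0],
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    identity=identity,
                )
            )
    return blocks


def _read_coords_tsv(path: str | os.PathLike) -> list[AlignmentBlock]:
    """show-coords -T layout: S1 E1 S2 E2 LEN1 LEN2 %IDY REF QUERY."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: coords TSV needs >= 9 columns")
            try:
                s1, e1, s2, e2 = (int(x) for x in f[:4])
                idy = float(f[6])
            except ValueError:
                if lineno <= 4:  # tolerate show-coords preamble/header lines
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate")
            strand = "+"
            if s2 > e2:
                strand = "-"
                s2, e2 = e2, s2
            blocks.append(
                AlignmentBlock(
                    ref_chrom=f[7],
                    ref_start=s1 - 1,
                    ref_end=e1,
                    query_chrom=f[8],
                    query_start=s2 - 1,
                    query_end=e2,
                    strand=strand,
                    identity=idy,
                )
            )
    return blocks


def write_paf(blocks: Sequence[AlignmentBlock], path: str | os.PathLike,
              chrom_lengths: dict[str, int] | None = None) -> None:
    chrom_lengths = chrom_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            aln_len = max(b.ref_length, b.query_length)
            matches = round(b.identity / 100.0 * aln_len)
            qlen = chrom_lengths.get(b.query_chrom, b.query_end)
            tlen = chrom_lengths.get(b.ref_chrom, b.ref_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_chrom, qlen, b.query_start, b.query_end, b.strand,
                        b.ref_chrom, tlen, b.ref_start, b.ref_end,
                        matches, aln_len, 60,
                    )
                )
                + "\n"
            )


def write_coords_tsv(blocks: Sequence[AlignmentBlock], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            s2, e2 = b.query_start + 1, b.query_end
            if b.strand == "-":
                s2, e2 = e2, s2
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.ref_start + 1, b.ref_end, s2, e2,
                        b.ref_length, b.query_length, f"{b.identity:.2f}",
                        b.ref_chrom, b.query_chrom,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample sex table and coverage tracks
# ---------------------------------------------------------------------------

def read_sex_table(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "sex"], dtype=str)
    out = {}
    for _, row in df.iterrows():
        sex = row["sex"].strip().upper()
        if sex not in ("M", "F"):
            raise FormatError(f"{path}: invalid sex {row['sex']!r} for {row['sample']}")
        out[row["sample"]] = sex
    return out


def write_sex_table(sexes: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, sex in sexes.items():
            fh.write(f"{sample}\t{sex}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": float},
    )
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise FormatError(f"{path}: invalid bedgraph interval")
    return df


def write_bedgraph(track: pd.DataFrame, path: str | os.PathLike) -> None:
    track.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "depth"], float_format="%g")
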