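"""Ground-truthed synthetic neo-XY populations.

The generator emulates the signal structure of a young neo-sex chromosome
system in a male-heterogametic species:

* an ``XL`` arm (ancestral X) that is hemizygous in males — half male
  coverage, (near-)zero male heterozygosity;
* a non-recombining neo-XY stratum on the fused arm — equal coverage in both
  sexes but elevated male heterozygosity because every fixed X-Y difference
  appears heterozygous in males;
* gametologous gene pairs inside the stratum, a fraction of whose neo-Y
  copies carry an ORF-disrupting mutation (premature stop or frameshift);
* sex-specific repeat annotations with configurable per-family abundances;
* whole-genome alignment block sets with known inversion / translocation /
  duplication events.

Every random draw flows from the single config seed, so identical configs
produce byte-identical output bundles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AlignmentBlock,
    GeneModel,
    GenomicInterval,
    Genotype,
    RepeatHit,
    VariantRecord,
    write_bed,
    write_bedgraph,
    write_coords_tsv,
    write_fasta,
    write_gff3,
    write_paf,
    write_repeatmasker_out,
    write_sex_table,
    write_vcf,
)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

_BASE_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


# shared Genotype instances: the simulator emits millions of biallelic
# phased genotypes, so interning them keeps bundle construction fast
_GT_CACHE: dict[tuple[int | None, int | None, bool], Genotype] = {}


def _gt(a: int | None, b: int | None, phased: bool = True) -> Genotype:
    key = (a, b, phased)
    g = _GT_CACHE.get(key)
    if g is None:
        g = _GT_CACHE[key] = Genotype((a, b), phased)
    return g


@dataclass(frozen=True)
class RepeatFamilyConfig:
    """Target abundance (percent of genome bases) per sex for one family."""

    family: str
    repeat_class: str
    male_percent: float
    female_percent: float
    mean_divergence: float
    sd_divergence: float = 1.0


@dataclass(frozen=True)
class RearrangementConfig:
    """Truth set for the alignment-block classifier.

    Blocks tile the reference chromosome; translocated blocks are relocated
    onto a second query scaffold, duplicated blocks appear as an extra
    reference copy mapping onto an existing query interval.
    """

    n_blocks: int = 24
    block_length: int = 50_000
    n_inversions: int = 2
    n_translocations: int = 3
    n_duplications: int = 1
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    ref_chrom: str = "anc_chr1"
    query_chrom: str = "neoY"
    query_chrom_alt: str = "neoY_frag"


def _default_repeat_families() -> tuple[RepeatFamilyConfig, ...]:
    return (
        RepeatFamilyConfig("satDNA-1", "Satellite", 3.3, 2.0, 2.0, 0.5),
        RepeatFamilyConfig("satDNA-2", "Satellite", 1.0, 1.0, 2.0, 0.5),
        RepeatFamilyConfig("Gypsy-1", "LTR/Gypsy", 20.0, 20.0, 20.0, 3.0),
        RepeatFamilyConfig("Mariner-1", "DNA/TcMar-Mariner", 8.0, 9.0, 15.0, 3.0),
        RepeatFamilyConfig("LINE-1", "LINE/L1", 10.0, 10.0, 25.0, 4.0),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic neo-XY population.

    Defaults model a 100 Mb genome in which the 10 Mb neo-X carries a 2 Mb
    hemizygous XL arm and a 2 Mb non-recombining stratum, sequenced at 20x
    in four males and four females, with 1% fixed X-Y divergence inside the
    stratum over a 0.1% polymorphism background.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("neoX", 10_000_000),
        ("chrA", 50_000_000),
        ("chrB", 40_000_000),
    )
    neox_chrom: str = "neoX"
    stratum: tuple[int, int] = (5_000_000, 7_000_000)
    xl_interval: tuple[int, int] | None = (0, 2_000_000)
    n_males: int = 4
    n_females: int = 4
    xy_snp_divergence: float = 0.01
    xy_indel_rate: float = 2e-4
    polymorphism_rate: float = 0.001
    pseudogenization_rate: float = 0.4
    mean_depth: float = 20.0
    n_genes_stratum: int = 30
    n_genes_background: int = 30
    gene_codon_range: tuple[int, int] = (100, 300)
    repeat_families: tuple[RepeatFamilyConfig, ...] = field(
        default_factory=_default_repeat_families
    )
    rearrangements: RearrangementConfig = field(default_factory=RearrangementConfig)
    coverage_bin: int = 1000

    def validate(self) -> None:
        lengths = dict(self.genome)
        if self.neox_chrom not in lengths:
            raise ValueError(f"genome lacks the neo-X chromosome {self.neox_chrom!r}")
        neox_len = lengths[self.neox_chrom]
        s0, s1 = self.stratum
        if not (0 <= s0 < s1 <= neox_len):
            raise ValueError("stratum must lie within the neo-X chromosome")
        if self.xl_interval is not None:
            x0, x1 = self.xl_interval
            if not (0 <= x0 < x1 <= neox_len):
                raise ValueError("xl_interval must lie within the neo-X chromosome")
            if max(s0, x0) < min(s1, x1):
                raise ValueError("xl_interval must not overlap the stratum")
        for rate in (
            self.xy_snp_divergence,
            self.xy_indel_rate,
            self.polymorphism_rate,
            self.pseudogenization_rate,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one sample of each sex")
        r = self.rearrangements
        n_events = r.n_inversions + r.n_translocations + r.n_duplications
        if n_events > r.n_blocks:
            raise ValueError("requested rearrangement events exceed available blocks")

    @property
    def samples(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_males)] + [
            f"F{i + 1}" for i in range(self.n_females)
        ]

    @property
    def sexes(self) -> dict[str, str]:
        return {s: ("M" if s.startswith("M") else "F") for s in self.samples}

    @property
    def stratum_interval(self) -> GenomicInterval:
        return GenomicInterval(self.neox_chrom, *self.stratum)


class _LazyReference(dict):
    """Chromosome -> sequence string, decoded from byte arrays on first use."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        super().__init__()
        self._arrays = arrays

    def __missing__(self, key: str) -> str:
        seq = self._arrays[key].tobytes().decode()
        self[key] = seq
        return seq

    def __iter__(self):
        return iter(self._arrays)

    def __len__(self):
        return len(self._arrays)

    def keys(self):
        return self._arrays.keys()

    def items(self):
        return ((k, self[k]) for k in self._arrays)

    def values(self):
        return (self[k] for k in self._arrays)


@dataclass
class SimBundle:
    """All outputs of one simulation run, with ground-truth labels."""

    config: SimConfig
    reference: dict[str, str]
    samples: list[str]
    sexes: dict[str, str]
    variants: list[VariantRecord]
    coverage: dict[str, pd.DataFrame]
    genes: list[GeneModel]
    gene_truth: dict[str, str]  # gene_id -> functional | pseudogenized
    male_y_hap: dict[str, int]  # sample -> haplotype index (0/1) carrying Y
    truth_regions: list[GenomicInterval]
    repeats: dict[str, list[RepeatHit]]  # 'M' / 'F'
    blocks: list[AlignmentBlock]
    block_truth: list[str]
    block_seq_pairs: list[tuple[str, str]]  # gapped (ref, query) per block

    def write(self, outdir: str | os.PathLike) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, out / "ref.fa")
        write_bed(self.truth_regions, out / "truth.bed")
        contigs = dict(self.config.genome)
        write_vcf(self.variants, self.samples, out / "variants.vcf", contigs)
        covdir = out / "coverage"
        covdir.mkdir(exist_ok=True)
        for sample, track in self.coverage.items():
            write_bedgraph(track, covdir / f"{sample}.bedgraph")
        write_gff3(self.genes, out / "genes.gff3")
        with open(out / "gene_truth.tsv", "w") as fh:
            for gid, label in self.gene_truth.items():
                fh.write(f"{gid}\t{label}\n")
        for sex, hits in self.repeats.items():
            write_repeatmasker_out(hits, out / f"repeats.{sex}.out")
        lengths = {
            self.config.rearrangements.ref_chrom:
                self.config.rearrangements.n_blocks
                * self.config.rearrangements.block_length * 2,
            self.config.rearrangements.query_chrom:
                self.config.rearrangements.n_blocks
                * self.config.rearrangements.block_length * 2,
            self.config.rearrangements.query_chrom_alt:
                self.config.rearrangements.n_blocks
                * self.config.rearrangements.block_length,
        }
        write_paf(self.blocks, out / "blocks.paf", lengths)
        write_coords_tsv(self.blocks, out / "blocks.coords.tsv")
        with open(out / "blocks_truth.tsv", "w") as fh:
            for i, label in enumerate(self.block_truth):
                fh.write(f"block{i}\t{label}\n")
        pair_seqs: dict[str, str] = {}
        for i, (r, q) in enumerate(self.block_seq_pairs):
            pair_seqs[f"block{i}_ref"] = r
            pair_seqs[f"block{i}_qry"] = q
        write_fasta(pair_seqs, out / "blocks.fa")
        write_sex_table(self.sexes, out / "sex.tsv")


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _random_internal_codons(n: int, rng: np.random.Generator) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in STOPS:
            out.append(codon)
    return out


@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    start: int
    strand: str
    codons: list[str]  # coding orientation, includes ATG and terminal stop
    truth: str  # functional | pseudogenized
    disruption: tuple | None = None  # ('stop', codon_idx) | ('frameshift', offset, kind, size)

    @property
    def length(self) -> int:
        return 3 * len(self.codons)

    @property
    def end(self) -> int:
        return self.start + self.length


def _plan_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_GenePlan]:
    plans: list[_GenePlan] = []
    lengths = dict(cfg.genome)
    s0, s1 = cfg.stratum
    lo, hi = cfg.gene_codon_range

    def place(n: int, chrom: str, lo_pos: int, hi_pos: int, prefix: str,
              pseudogenize: bool) -> None:
        taken: list[tuple[int, int]] = []
        for k in range(n):
            n_codons = int(rng.integers(lo, hi + 1))
            glen = 3 * n_codons
            for _ in range(200):
                start = int(rng.integers(lo_pos, hi_pos - glen))
                if all(start + glen + 50 < s or start > e + 50 for s, e in taken):
                    break
            else:
                raise ValueError("could not place genes without overlap")
            taken.append((start, start + glen))
            strand = "+" if rng.random() < 0.7 else "-"
            codons = ["ATG"] + _random_internal_codons(n_codons - 2, rng) + ["TAA"]
            truth = "functional"
            disruption = None
            if pseudogenize and rng.random() < cfg.pseudogenization_rate:
                truth = "pseudogenized"
                cidx = int(rng.integers(5, n_codons - 5))
                if rng.random() < 0.5:
                    codons[cidx] = "TAC"  # one substitution away from TAA
                    disruption = ("stop", cidx)
                else:
                    size = int(rng.integers(1, 3))
                    kind = "del" if rng.random() < 0.5 else "ins"
                    disruption = ("frameshift", 3 * cidx, kind, size)
            plans.append(
                _GenePlan(f"{prefix}{k + 1:03d}", chrom, start, strand, codons,
                          truth, disruption)
            )

    margin = 2000
    place(cfg.n_genes_stratum, cfg.neox_chrom, s0 + margin, s1 - margin,
          "gene_str_", pseudogenize=True)
    # background genes: split between the neo-X PAR (right of the stratum if
    # room, else left) and the first autosome
    n_par = cfg.n_genes_background // 2
    neox_len = lengths[cfg.neox_chrom]
    if neox_len - s1 > 1_000_000:
        place(n_par, cfg.neox_chrom, s1 + margin, neox_len - margin,
              "gene_par_", pseudogenize=False)
    else:
        xl1 = cfg.xl_interval[1] if cfg.xl_interval else 0
        place(n_par, cfg.neox_chrom, xl1 + margin, s0 - margin,
              "gene_par_", pseudogenize=False)
    autosomes = [c for c, _ in cfg.genome if c != cfg.neox_chrom]
    if autosomes:
        place(cfg.n_genes_background - n_par, autosomes[0], margin,
              lengths[autosomes[0]] - margin, "gene_aut_", pseudogenize=False)
    return plans


def _safe_alt(ref_base: str, pos: int, plan: "_GenePlan | None",
              rng: np.random.Generator, seq: np.ndarray) -> str:
    """Alternative base at ``pos`` that never creates a stop codon in any
    overlapping gene's reading frame (keeps 'functional' truth labels exact)."""
    alts = [b for b in BASES if b != ref_base]
    rng.shuffle(alts)
    if plan is None:
        return alts[0]
    off = pos - plan.start  # offset in genomic orientation
    codon_start = plan.start + 3 * (off // 3)
    codon = bytes(seq[codon_start:codon_start + 3]).decode()
    within = off % 3
    for alt in alts:
        mutated = codon[:within] + alt + codon[within + 1:]
        if plan.strand == "-":
            mutated = mutated.translate(COMPLEMENT)[::-1]
        if mutated not in STOPS:
            return alt
    return ref_base  # unreachable for the standard code; keeps caller total


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_neo_xy(config: SimConfig) -> SimBundle:
    """Generate a full ground-truthed bundle; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.genome)
    samples = config.samples
    n_m, n_f = config.n_males, config.n_females
    n_samples = n_m + n_f

    # --- gene plans and reference sequences -------------------------------
    plans = _plan_genes(config, rng)
    plans_by_chrom: dict[str, list[_GenePlan]] = {}
    for p in plans:
        plans_by_chrom.setdefault(p.chrom, []).append(p)
    for ps in plans_by_chrom.values():
        ps.sort(key=lambda p: p.start)

    seqs: dict[str, np.ndarray] = {}
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in config.genome:
        seqs[chrom] = base_arr[rng.integers(0, 4, length, dtype=np.uint8)]
    for p in plans:
        cds = "".join(p.codons)
        if p.strand == "-":
            cds = cds.translate(COMPLEMENT)[::-1]
        seqs[p.chrom][p.start:p.end] = np.frombuffer(cds.encode(), dtype=np.uint8)

    def plan_lookup(chrom: str, pos: int) -> _GenePlan | None:
        for p in plans_by_chrom.get(chrom, ()):
            if p.start <= pos < p.end:
                return p
            if p.start > pos:
                break
        return None

    male_y_hap = {s: int(rng.integers(0, 2)) for s in samples[:n_m]}
    s0, s1 = config.stratum
    xl = config.xl_interval

    records: list[VariantRecord] = []
    blocked: dict[str, set[int]] = {c: set() for c in lengths}

    # --- ORF-disrupting variants on the Y haplotype -----------------------
    def male_xy_genotypes() -> list[Genotype]:
        gts = [_gt(0, 1) if male_y_hap[s] == 1 else _gt(1, 0) for s in samples[:n_m]]
        gts += [_gt(0, 0)] * n_f
        return gts

    def site_depths(chrom: str, pos: int) -> list[int | None]:
        lam = np.full(n_samples, config.mean_depth)
        if xl is not None and chrom == config.neox_chrom and xl[0] <= pos < xl[1]:
            lam[:n_m] /= 2.0
        return [int(d) for d in rng.poisson(lam)]

    def add_record(chrom: str, start: int, ref: str, alt: str,
                   genotypes: list[Genotype]) -> None:
        records.append(
            VariantRecord(
                chrom=chrom, start=start, ref=ref, alts=(alt,),
                qual=float(rng.uniform(50, 200)), genotypes=genotypes,
                depths=site_depths(chrom, start), gqs=[99] * n_samples,
            )
        )
        for off in range(len(ref)):
            blocked[chrom].add(start + off)

    for p in plans:
        if p.disruption is None:
            continue
        seq = seqs[p.chrom]
        if p.disruption[0] == "stop":
            cidx = p.disruption[1]
            # TAC -> TAA via a substitution at the codon's third base
            if p.strand == "+":
                gpos = p.start + 3 * cidx + 2
                ref_b, alt_b = "C", "A"
            else:
                gpos = p.end - 1 - (3 * cidx + 2)
                ref_b, alt_b = "G", "T"
            assert chr(seq[gpos]) == ref_b
            add_record(p.chrom, gpos, ref_b, alt_b, male_xy_genotypes())
        else:
            _, coff, kind, size = p.disruption
            anchor = p.start + coff
            anchor_b = chr(seq[anchor])
            if kind == "del":
                ref = anchor_b + bytes(seq[anchor + 1:anchor + 1 + size]).decode()
                alt = anchor_b
            else:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size))
                ref = anchor_b
                alt = anchor_b + ins
            add_record(p.chrom, anchor, ref, alt, male_xy_genotypes())

    # --- X-Y indels inside the stratum, outside CDS -----------------------
    neox = config.neox_chrom
    n_xy_indels = rng.binomial(s1 - s0, config.xy_indel_rate)
    indel_pos = np.sort(rng.integers(s0, s1 - 12, n_xy_indels))
    for pos in indel_pos:
        pos = int(pos)
        if plan_lookup(neox, pos) or plan_lookup(neox, pos + 11):
            continue
        if any((pos + d) in blocked[neox] for d in range(12)):
            continue
        size = int(rng.integers(1, 11))
        anchor_b = chr(seqs[neox][pos])
        if rng.random() < 0.5:
            ref = anchor_b + bytes(seqs[neox][pos + 1:pos + 1 + size]).decode()
            alt = anchor_b
        else:
            ref = anchor_b
            alt = anchor_b + "".join(BASES[i] for i in rng.integers(0, 4, size))
        add_record(neox, pos, ref, alt, male_xy_genotypes())

    def site_alleles(chrom: str, pos: np.ndarray) -> tuple[list[str], list[str]]:
        """Vectorized ref/alt bases; stop-safe alts inside gene CDS."""
        seq = seqs[chrom]
        code = _BASE_CODE[seq[pos]]
        alt_code = (code + rng.integers(1, 4, len(pos))) % 4
        refs = [BASES[c] for c in code]
        alts = [BASES[c] for c in alt_code]
        plist = plans_by_chrom.get(chrom, [])
        if plist:
            gstarts = np.array([p.start for p in plist], dtype=np.int64)
            gends = np.array([p.end for p in plist], dtype=np.int64)
            gi = np.searchsorted(gstarts, pos, side="right") - 1
            in_gene = (gi >= 0) & (pos < gends[np.clip(gi, 0, None)])
            for k in np.nonzero(in_gene)[0]:
                alts[k] = _safe_alt(refs[k], int(pos[k]), plist[gi[k]], rng, seq)
        return refs, alts

    # --- fixed X-Y SNP differences in the stratum -------------------------
    n_fixed = rng.binomial(s1 - s0, config.xy_snp_divergence)
    fixed_pos = np.unique(rng.integers(s0, s1, n_fixed))
    if blocked[neox]:
        fixed_pos = np.setdiff1d(
            fixed_pos, np.fromiter(blocked[neox], dtype=np.int64)
        )
    fixed_gts = male_xy_genotypes()
    f_refs, f_alts = site_alleles(neox, fixed_pos)
    f_quals = rng.uniform(50, 200, len(fixed_pos)).tolist()
    f_depths = rng.poisson(config.mean_depth, (len(fixed_pos), n_samples)).tolist()
    gq_row = [99] * n_samples
    for i, pos in enumerate(fixed_pos):
        records.append(
            VariantRecord(
                chrom=neox, start=int(pos), ref=f_refs[i], alts=(f_alts[i],),
                qual=f_quals[i], genotypes=list(fixed_gts),
                depths=f_depths[i], gqs=list(gq_row),
            )
        )
        blocked[neox].add(int(pos))

    # --- neutral polymorphism genome-wide ---------------------------------
    # candidate sites at twice the target per-sample heterozygosity; each
    # haplotype carries the alternative allele with probability 1/2, so the
    # per-site heterozygosity of a diploid sample equals polymorphism_rate
    _gt_by_code = [_gt(0, 0), _gt(0, 1), _gt(1, 0), _gt(1, 1)]
    for chrom, length in config.genome:
        n_cand = rng.binomial(length, 2.0 * config.polymorphism_rate)
        pos = np.unique(rng.integers(0, length, n_cand))
        if blocked[chrom]:
            blk = np.fromiter(blocked[chrom], dtype=np.int64)
            pos = np.setdiff1d(pos, blk, assume_unique=False)
        n_sites = len(pos)
        if n_sites == 0:
            continue
        hap = (rng.random((n_sites, n_samples, 2)) < 0.5).astype(np.int8)
        if xl is not None and chrom == neox:
            in_xl = (pos >= xl[0]) & (pos < xl[1])
            # hemizygous males: a single X haplotype, reported as homozygous
            hap[np.ix_(in_xl.nonzero()[0], range(n_m))] = hap[
                np.ix_(in_xl.nonzero()[0], range(n_m))
            ][:, :, :1]
        keep = hap.reshape(n_sites, -1).any(axis=1)
        pos, hap = pos[keep], hap[keep]
        quals = rng.uniform(50, 200, len(pos)).tolist()
        lam = np.full((len(pos), n_samples), config.mean_depth)
        if xl is not None and chrom == neox:
            in_xl = (pos >= xl[0]) & (pos < xl[1])
            lam[in_xl, :n_m] /= 2.0
        depths = rng.poisson(lam)
        refs, alts = site_alleles(chrom, pos)
        gt_codes = (2 * hap[:, :, 0] + hap[:, :, 1]).tolist()
        depth_list = depths.tolist()
        for i, p in enumerate(pos):
            gts = [_gt_by_code[c] for c in gt_codes[i]]
            records.append(
                VariantRecord(
                    chrom=chrom, start=int(p), ref=refs[i], alts=(alts[i],),
                    qual=quals[i], genotypes=gts,
                    depths=depth_list[i], gqs=list(gq_row),
                )
            )

    chrom_order = {c: i for i, (c, _) in enumerate(config.genome)}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.start))

    # --- coverage tracks --------------------------------------------------
    coverage: dict[str, pd.DataFrame] = {}
    bin_ = config.coverage_bin
    for si, sample in enumerate(samples):
        frames = []
        for chrom, length in config.genome:
            starts = np.arange(0, length, bin_, dtype=np.int64)
            ends = np.minimum(starts + bin_, length)
            widths = (ends - starts).astype(float)
            lam = config.mean_depth * widths
            if xl is not None and chrom == neox and si < n_m:
                ov = np.clip(np.minimum(ends, xl[1]) - np.maximum(starts, xl[0]), 0, None)
                lam = config.mean_depth * (widths - 0.5 * ov)
            depth = rng.poisson(lam) / widths
            frames.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": depth}
            ))
        coverage[sample] = pd.concat(frames, ignore_index=True)

    # --- gene models and truth --------------------------------------------
    genes = [
        GeneModel(p.gene_id, p.chrom, p.strand, ((p.start, p.end),), (0,))
        for p in plans
    ]
    gene_truth = {p.gene_id: p.truth for p in plans}

    # --- repeats ----------------------------------------------------------
    repeats = {
        sex: _simulate_repeats(config, sex, rng) for sex in ("M", "F")
    }

    # --- rearranged alignment blocks --------------------------------------
    blocks, block_truth, seq_pairs = emit_rearranged_blocks(config.rearrangements, rng)

    truth_regions = [GenomicInterval(neox, s0, s1, name="heterogametic")]
    if xl is not None:
        truth_regions.append(GenomicInterval(neox, xl[0], xl[1], name="homogametic"))

    reference = _LazyReference(seqs)
    return SimBundle(
        config=config, reference=reference, samples=samples, sexes=config.sexes,
        variants=records, coverage=coverage, genes=genes, gene_truth=gene_truth,
        male_y_hap=male_y_hap, truth_regions=truth_regions, repeats=repeats,
        blocks=blocks, block_truth=block_truth, block_seq_pairs=seq_pairs,
    )


def _simulate_repeats(config: SimConfig, sex: str,
                      rng: np.random.Generator) -> list[RepeatHit]:
    """Tile each 1 Mb window with non-overlapping hits whose total length
    matches the family's target percent, so merged densities hit the target."""
    hits: list[RepeatHit] = []
    window = 1_000_000
    total_pct = sum(
        (f.male_percent if sex == "M" else f.female_percent)
        for f in config.repeat_families
    )
    if total_pct >= 95:
        raise ValueError("repeat family abundances exceed the genome")
    for chrom, length in config.genome:
        for wstart in range(0, length, window):
            wlen = min(window, length - wstart)
            lengths_all: list[int] = []
            fams: list[RepeatFamilyConfig] = []
            for fam in config.repeat_families:
                pct = fam.male_percent if sex == "M" else fam.female_percent
                target = pct / 100.0 * wlen
                n_h = max(1, round(target / 2000)) if target > 0 else 0
                if n_h == 0:
                    continue
                ls = rng.integers(1500, 2500, n_h)
                ls = np.maximum(1, np.round(ls * target / ls.sum()).astype(int))
                lengths_all.extend(int(x) for x in ls)
                fams.extend([fam] * len(ls))
            n_hits = len(lengths_all)
            free = wlen - int(np.sum(lengths_all))
            if free < 0:
                raise ValueError("repeat targets exceed window size")
            order = rng.permutation(n_hits)
            gaps = rng.multinomial(free, [1.0 / (n_hits + 1)] * (n_hits + 1))
            divs = np.clip(
                rng.normal([fams[i].mean_divergence for i in order],
                           [fams[i].sd_divergence for i in order]),
                0.0, 100.0,
            )
            strands = rng.random(n_hits) < 0.5
            cursor = wstart
            for gi, oi in enumerate(order):
                cursor += int(gaps[gi])
                L = lengths_all[oi]
                fam = fams[oi]
                hits.append(RepeatHit(
                    GenomicInterval(chrom, cursor, cursor + L,
                                    "+" if strands[gi] else "-"),
                    fam.family, fam.repeat_class, float(divs[gi]),
                ))
                cursor += L
    return hits


# ---------------------------------------------------------------------------
# rearranged alignment blocks
# ---------------------------------------------------------------------------

def emit_rearranged_blocks(
    rcfg: RearrangementConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[AlignmentBlock], list[str], list[tuple[str, str]]]:
    """Emit alignment blocks with known event labels plus gapped sequence
    pairs carrying the configured SNP/indel rates.

    Returns ``(blocks, truth_labels, aligned_pairs)`` where truth labels are
    ``syntenic | inversion | translocation | duplication`` and each aligned
    pair is an equal-length gapped (reference, query) string tuple.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rcfg.n_blocks
    L = rcfg.block_length
    n_events = rcfg.n_inversions + rcfg.n_translocations + rcfg.n_duplications
    if n_events > n:
        raise ValueError("requested rearrangement events exceed available blocks")
    event_idx = rng.choice(n, size=n_events, replace=False)
    inv_idx = set(int(i) for i in event_idx[:rcfg.n_inversions])
    tra_idx = set(int(i) for i in
                  event_idx[rcfg.n_inversions:rcfg.n_inversions + rcfg.n_translocations])
    dup_src = [int(i) for i in event_idx[rcfg.n_inversions + rcfg.n_translocations:]]

    blocks: list[AlignmentBlock] = []
    truth: list[str] = []
    pairs: list[tuple[str, str]] = []
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    tra_slot = 0

    def make_pair(length: int, inverted: bool) -> tuple[str, str, float]:
        ref = base_arr[rng.integers(0, 4, length)]
        qry = ref.copy()
        n_snp = rng.binomial(length, rcfg.snp_rate)
        snp_pos = np.unique(rng.integers(0, length, n_snp))
        for p in snp_pos:
            cur = chr(qry[p])
            alt = BASES[(BASES.index(cur) + int(rng.integers(1, 4))) % 4]
            qry[p] = ord(alt)
        ref_s, qry_s = ref.tobytes().decode(), qry.tobytes().decode()
        n_ind = rng.binomial(length, rcfg.indel_rate)
        ind_pos = sorted(
            (int(p) for p in np.unique(rng.integers(1, length - 12, max(n_ind, 0)))),
            reverse=True,
        )
        ref_l, qry_l = list(ref_s), list(qry_s)
        for p in ind_pos:
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion in query
                qry_l[p:p + size] = ["-"] * size
            else:  # insertion in query
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size))
                ref_l[p:p] = ["-"] * size
                qry_l[p:p] = list(ins)
        ref_g, qry_g = "".join(ref_l), "".join(qry_l)
        ra = np.frombuffer(ref_g.encode(), dtype=np.uint8)
        qa = np.frombuffer(qry_g.encode(), dtype=np.uint8)
        matches = int(((ra == qa) & (ra != ord("-"))).sum())
        identity = 100.0 * matches / len(ref_g)
        return ref_g, qry_g, identity

    for i in range(n):
        ref_start = i * L
        inverted = i in inv_idx
        ref_g, qry_g, identity = make_pair(L, inverted)
        qlen = len(qry_g) - qry_g.count("-")
        if i in tra_idx:
            qchrom = rcfg.query_chrom_alt
            qstart = tra_slot * (L + L // 2)
            tra_slot += 1
            label = "translocation"
        else:
            qchrom = rcfg.query_chrom
            qstart = ref_start
            label = "inversion" if inverted else "syntenic"
        blocks.append(AlignmentBlock(
            ref_chrom=rcfg.ref_chrom, ref_start=ref_start, ref_end=ref_start + L,
            query_chrom=qchrom, query_start=qstart, query_end=qstart + qlen,
            strand="-" if inverted else "+", identity=identity,
        ))
        truth.append(label)
        pairs.append((ref_g, qry_g))

    # duplications: an extra reference copy aligning onto the query interval
    # of an existing syntenic block
    syntenic = [i for i in range(n) if truth[i] == "syntenic"]
    for k, _src in enumerate(dup_src):
        src = syntenic[int(rng.integers(0, len(syntenic)))]
        ref_g, qry_g, identity = make_pair(L, False)
        qlen = len(qry_g) - qry_g.count("-")
        b_src = blocks[src]
        blocks.append(AlignmentBlock(
            ref_chrom=rcfg.ref_chrom,
            ref_start=n * L + k * (L + L // 2),
            ref_end=n * L + k * (L + L // 2) + L,
            query_chrom=b_src.query_chrom,
            query_start=b_src.query_start,
            query_end=b_src.query_start + qlen,
            strand="+", identity=identity,
        ))
        truth.append("duplication")
        pairs.append((ref_g, qry_g))
    return blocks, truth, pairs


# ---------------------------------------------------------------------------
# small focused generators used by the validation suite
# ---------------------------------------------------------------------------

FOURFOLD_PREFIXES = ("GC", "GT", "AC", "CC", "GG")


def simulate_synonymous_pair(
    n_codons: int, d_syn: float, rng: np.random.Generator | int | None = None
) -> tuple[str, str]:
    """A codon pair diverged only at synonymous sites with true distance ``d_syn``.

    Codons are drawn from five 4-fold-degenerate families whose first and
    second positions have no synonymous single-nucleotide neighbours, so each
    codon contributes exactly one synonymous site and all differences are
    third-position synonymous changes. Third positions evolve under a
    Jukes-Cantor process: P(difference) = 3/4 * (1 - exp(-4 d/3)).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * d_syn / 3.0))
    x_codons, y_codons = [], []
    for _ in range(n_codons):
        prefix = FOURFOLD_PREFIXES[int(rng.integers(0, len(FOURFOLD_PREFIXES)))]
        third = BASES[int(rng.integers(0, 4))]
        x_codons.append(prefix + third)
        if rng.random() < p_diff:
            others = [b for b in BASES if b != third]
            y_codons.append(prefix + others[int(rng.integers(0, 3))])
        else:
            y_codons.append(prefix + third)
    return "".join(x_codons), "".join(y_codons)


def simulate_y_copies(
    n_genes: int,
    pseudogenization_rate: float,
    rng: np.random.Generator | int | None = None,
    codon_range: tuple[int, int] = (100, 300),
    background_sub_rate: float = 0.005,
) -> list[tuple[str, str, str]]:
    """Parent CDS / neo-Y copy pairs with known functional status.

    Returns ``(parent_cds, y_cds, truth)`` tuples where truth is
    ``functional`` or ``pseudogenized``. Background X-Y substitutions never
    create stops; functional copies occasionally carry a whole-codon in-frame
    deletion, which leaves the ORF intact.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = _codon_table()
    out = []
    for _ in range(n_genes):
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        codons = ["ATG"] + _random_internal_codons(n_codons - 2, rng) + ["TAA"]
        y = list(codons)
        # background substitutions, avoiding new stops
        n_sub = rng.binomial(3 * n_codons, background_sub_rate)
        for pos in np.unique(rng.integers(3, 3 * (n_codons - 1), max(n_sub, 0))):
            ci, off = divmod(int(pos), 3)
            codon = y[ci]
            alts = [b for b in BASES if b != codon[off]]
            rng.shuffle(alts)
            for alt in alts:
                cand = codon[:off] + alt + codon[off + 1:]
                if cand not in STOPS:
                    y[ci] = cand
                    break
        truth = "functional"
        if rng.random() < pseudogenization_rate:
            truth = "pseudogenized"
            cidx = int(rng.integers(2, n_codons - 2))
            if rng.random() < 0.5:
                y[cidx] = STOPS[int(rng.integers(0, 3))]
            else:
                seq = "".join(y)
                size = int(rng.integers(1, 3))
                pos = int(rng.integers(3, len(seq) - 6))
                if rng.random() < 0.5:
                    seq = seq[:pos] + seq[pos + size:]
                else:
                    ins = "".join(BASES[i] for i in rng.integers(0, 4, size))
                    seq = seq[:pos] + ins + seq[pos:]
                out.append(("".join(codons), seq, truth))
                continue
        elif rng.random() < 0.2 and n_codons > 10:
            cidx = int(rng.integers(2, n_codons - 2))
            del y[cidx]  # in-frame whole-codon deletion: ORF intact
        out.append(("".join(codons), "".join(y), truth))
    return out
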