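# Methods

`neoxy` implements a desk-scale pipeline for characterizing young neo-sex
chromosomes from population resequencing summaries: per-sample coverage
tracks, multi-sample phased genotypes, gene models, repeat annotations and
whole-genome alignment blocks. This note records the models, the parameter
choices, the numerical conventions and the known limits of each stage.

## The biological signal model

In a male-heterogametic neo-XY system formed by an X–autosome fusion, three
signatures separate the chromosome classes in male/female contrasts:

* **Hemizygosity (XL / ancestral X).** Males carry one copy: the
  male/female depth ratio is ~0.5 and male heterozygosity is ~0.
* **Non-recombining stratum (neo-XR vs neo-Y).** Both sexes are diploid
  (ratio ~1), but every fixed X–Y difference is heterozygous in every male,
  so male heterozygosity ≈ fixed divergence + polymorphism while female
  heterozygosity stays at the polymorphism level.
* **Autosomes / PAR.** Ratio ~1 and equal heterozygosity in both sexes.

All downstream stages consume or exploit this structure; the synthetic-data
generator (below) produces it with known truth labels.

## Windowed sex-difference scan (`neoxy.scan`)

Coverage is averaged per window and normalized by each sample's genome-wide
median window depth, so the autosomal expectation is 1.0 regardless of
sequencing effort; this achieves cross-sample comparability without read
subsampling. Heterozygosity is heterozygous calls divided by callable sites,
where a site is callable when every sample reaches a minimum depth (default
3); windows with fewer than `min_callable` callable sites report missing
heterozygosity.

Outlier windows are flagged against the empirical percentile band of each
statistic's genome-wide distribution (default 95%). The band uses symmetric
*order statistics* rather than interpolated quantiles: the k-th smallest and
k-th largest window values with k = ⌊α/2·(n−1)⌋. This makes the band
equivariant under monotone transforms, so relabelling the sexes swaps
low/high flags exactly, and keeps the expected flagged fraction at ≈ α under
homogeneity. A percentile band was chosen because it is assumption-free; it
can only resolve an outlier class that occupies less than α/2 of the genome's
windows, which holds for sex-linked arms in realistic karyotypes (a few
percent of the genome) and is respected by the simulator's default genome.

Regions are called from runs of flagged windows (`min_run` = 3 flagged
windows, at most `max_gap` = 1 unflagged window inside a run): `het_high`
runs are heterogametic candidates, `cov_low` runs homogametic candidates.
Classification thresholds — coverage ratio ≤ 0.75 for hemizygous, within
[0.85, 1.15] for diploid, male heterozygosity ≥ 1.5× female for a
heterogametic call — are set so the theoretical signals (ratio 0.5; het =
divergence + polymorphism vs polymorphism alone) sit far inside the accept
regions; all are exposed as function arguments. Candidates with hemizygous
coverage but excess male heterozygosity are conflicting evidence and are
emitted as homogametic with a warning; candidates matching neither rule are
dropped with a warning.

## Variant filter cascade (`neoxy.phase.filter_variants`)

Six hard-filter rules, applied in order with the first violated rule
recorded per record:

1. site QUAL < 30 or total site depth < 3 reads;
2. any heterozygous genotype with depth < 4;
3. any homozygous genotype with site QUAL < 50 and depth < 4;
4. a heterozygous site with QUAL < 2 × mean depth;
5. maximum genotype depth > mean depth + 3·√(mean depth) (copy-number /
   paralog suspects);
6. overlap with a repeat mask.

"Mean depth" in rules 4–5 is the mean of all non-missing genotype depths
across the records surviving rules 1–3 — a dataset-wide constant, so the
filter is independent of input order. Rule 5 is applied to every record
(any depth spike is a CNV suspect regardless of zygosity).

## Haplotype clustering and haploid regenotyping

Within a candidate heterogametic region, every sample contributes two phased
haplotype rows over the filtered variant sites (phase is a hard
precondition for heterozygous male genotypes; phasing itself is upstream of
this package). Distances are mismatch fractions over co-called sites; pairs
sharing fewer than `min_sites` (default 20) sites get the mean defined
distance. Average-linkage hierarchical clustering is cut into two clusters.
The *Y-cluster criterion* comes directly from the biology: exactly one
haplotype from every male and no female haplotype. The assignment is
accepted when the criterion holds and the between/within mean-distance ratio
reaches `min_separation` (default 3.0) — with fixed X–Y divergence d over
polymorphism π the expected ratio is ≈ (d + π)/π, so the default accepts
d ≥ 2π with margin at typical site counts. Failing the criterion yields
`ambiguous`; insufficient separation or no divergence yields `rejected`.

Regenotyping maps each male's phased genotype a|b to a haploid X call (the
non-Y haplotype) and a haploid Y call; females contribute both haplotypes to
the X panel. Gametolog CDS extraction substitutes the majority haploid
allele (ties fall back to the reference) into the reference CDS, applying
indels from 3′ to 5′ so coordinates stay valid; minus-strand genes are
reverse-complemented into coding orientation. Genes whose CDS span crosses a
region boundary are conservatively assigned to the PAR.

## Divergence (`neoxy.dnds`)

Gametolog pairs are aligned by global Needleman–Wunsch over *codon units*
(+2 amino-acid match, −1 mismatch, −4 per codon gap; ties broken diagonal >
up > left), which keeps gaps in frame by construction. The dynamic program
is row-vectorized: the in-row gap recurrence is unrolled into a running
maximum (max-plus scan), giving exact DP scores at numpy speed.

dN/dS uses Nei–Gojobori (1986) counting: per codon position, synonymous
sites are (synonymous single-nucleotide neighbours)/3 — mutations to stop
codons count as nonsynonymous — averaged between the two codons, so
N + S = 3 per codon. Multi-substitution codons average synonymous and
nonsynonymous steps over all orderings of the minimal mutation paths,
excluding paths through stop codons; codons where every path hits a stop are
dropped and flagged. Proportions are Jukes–Cantor corrected,
d = −¾·ln(1 − 4p/3), undefined for p ≥ ¾ (flagged `jc_undefined`). A
counting method is used deliberately: the pipeline's divergence summaries
are descriptive (medians, saturation filters, a two-sample test), for which
NG86 is standard and transparent; maximum-likelihood codon models are out of
scope. Pairs with dS ≥ 2 or dN/dS ≥ 10 are discarded as saturated; dS = 0
pairs are kept for dS summaries but excluded from dN/dS summaries. Regional
comparisons use Welch's unequal-variance t-test (two-sided, with the
Welch–Satterthwaite degrees of freedom).

## Pseudogene calls (`neoxy.pseudogene`)

A neo-Y copy is compared directly to its annotated parent CDS (parentage is
known in this data model, so no homology search is needed). Scanning the
alignment 5′→3′, a *frameshift* is recorded at each gap run after which the
cumulative candidate-minus-parent length offset leaves frame (mod 3 ≠ 0); a
later compensating gap restores the frame but the event still counts — the
intervening peptide is garbled, so the copy is nonfunctional regardless. A
*premature stop* is any stop codon read in the candidate's own running frame
(equivalently, the frame implied by upstream cumulative gaps) whose aligned
parent position lies strictly before the parent's terminal codon. The copy
is `nonfunctional` iff any disruption exists. The degeneration level of a
region is the fraction of nonfunctional copies with an exact (Clopper–
Pearson) binomial interval.

## Rearrangements (`neoxy.rearrange`)

Blocks are filtered at ≥ 95% identity and ≥ 2 kb reference length, the
conventional thresholds for whole-genome alignment curation. SNPs are
mismatching non-gap columns; an indel is a maximal gap run in either
sequence, counted as one event (the event, not its length, is the natural
unit for per-Mb tallies). Per-Mb medians are taken over the 1 Mb reference
bins intersecting the blocks.

Classification is a deliberately simple order/orientation/copy scheme, not a
full structural-variant model: reference↔query chromosome correspondence is
the pairing carrying the most aligned bases; the collinear backbone is the
longest strictly increasing subsequence of query positions (forward-strand
blocks on the corresponding chromosome, in reference order); rules apply in
priority order *duplication* (query interval overlapping ≥ 50% of another
block's query interval — of two such blocks, the one outside the backbone is
the duplication; if neither is in the backbone the later, shorter copy is) >
*inversion* (reverse strand on the corresponding chromosome) > *syntenic*
(backbone member) > *translocation* (everything else). The scheme is
validated only against this package's own simulator; nested and complex
events (inverted translocations, tandem expansions) are out of scope.

## Repeats (`neoxy.repeats`)

Window densities merge overlapping hits so each base counts once.
Sex-differential enrichment compares per-family abundance (percent of
assayed bases) between male and female genomes; both directional ratios are
reported and the 1.1× threshold is inclusive (≥), with a family absent from
one sex reported as enriched with an infinite ratio. Divergence landscapes
histogram abundance in 1% divergence bins, so young, homogeneous families
(satellites) pile up near zero while older TE families sit at higher
divergence. Region-vs-genome density contrasts use the Mann–Whitney U test,
two-sided with continuity correction, switching to exact enumeration when
both sides have ≤ 8 windows and no ties.

## The synthetic-data generator (`neoxy.simulate`)

The generator emulates the study conditions, not reads: coverage is Poisson
read counts over 1 kb bins (divided by bin length), halved for males inside
the XL interval — mapping and read-level noise are out of scope, and the
scan consumes depth tracks. Genotypes are emitted phased, with each male's
X/Y haplotype order permuted per sample so downstream clustering cannot rely
on emission order. Polymorphism is parameterized by the per-site, per-sample
heterozygosity π: candidate sites arise at rate 2π and each haplotype
carries the alternative allele with probability ½. Fixed X–Y differences
are uniform in the stratum; X–Y indels are 1–10 bp, placed outside CDS.
Pseudogenization injects, with equal probability, one premature stop (a
codon one substitution from TAA, pre-placed at gene construction, then
mutated through the VCF) or one 1–2 bp frameshift indel at a uniform CDS
position. Substitutions falling inside any CDS choose an alternative base
that never creates a stop in the gene's frame, so `functional` truth labels
are exact. Repeat hits tile each 1 Mb window to the family's target percent
without overlap (so merged densities hit the target); divergences are
normal per family. Rearranged blocks tile a reference chromosome;
translocations relocate blocks to a second query scaffold, duplications add
an extra reference copy of an existing query interval, inversions flip
strand in place.

Default conditions: a 100 Mb genome (neo-X 10 Mb carrying a 2 Mb XL arm and
a 2 Mb stratum, plus 50 + 40 Mb autosomes), 4 males + 4 females at 20×
depth, fixed X–Y divergence 0.01/site, polymorphism 0.001/site,
pseudogenization rate 0.4, five repeat families (two satellites near 2%
divergence, three TE families at 15–25%) with a male-biased satellite
(3.3% vs 2.0%) and a female-biased DNA transposon (9% vs 8%), and 24
alignment blocks of 50 kb with 2 inversions, 3 translocations and 1
duplication. The autosome sizes keep each sex-linked arm below the 2.5%
window fraction that a 95% percentile band can resolve, mirroring real
karyotypes where those arms are a small fraction of the genome.

Two focused generators serve the validation suite: `simulate_synonymous_pair`
builds codon pairs from five 4-fold-degenerate families whose first/second
positions have no synonymous neighbours, evolving third positions under a
Jukes–Cantor process with known distance — every difference is synonymous
and S is exactly one site per codon, so dS is directly comparable to the
generating distance; `simulate_y_copies` emits parent/Y CDS pairs with known
functional status (background substitutions stop-safe; functional copies may
carry whole-codon in-frame deletions).

All randomness flows from the single config seed; identical configs produce
byte-identical output files.

## What passing tests do and do not show

The simulator injects clean, unambiguous signals: uniform divergence, exact
hemizygosity, Poisson depth, error-free genotypes, unambiguous ORF
disruptions, non-overlapping rearrangement events at least 2× the length
filter. Passing the suite shows the machinery is correct under those
conditions. Real data add mapping bias in diverged regions, reference bias
on the Y, genotyping and phasing errors, segmental duplications that mimic
coverage loss, and nested rearrangements — none of which are modelled, so
accuracy on real genomes will be lower and threshold tuning per dataset
remains necessary.

## Problem sizes used by the validation suite

The bundled suite and the acceptance script run the scan on the default
100 Mb genome (20 replicate seeds), the gametolog stage on 1 Mb
neo-X-only populations (20 seeds), the dS oracle on 300-codon pairs
(50 replicates), pseudogene truth on 200 simulated copies, and the block
classifier on 20-block sets (20 seeds) — sizes at which every expectation
check has comfortable statistical power while a full run stays in the
minutes range on one CPU.

## Known limitations

* Phasing is a precondition, not a stage: switch errors in the input phase
  directly degrade haplotype clustering.
* The X/Y consensus uses a majority rule per site; at polymorphic sites
  with few haplotypes this injects occasional polymorphism-derived
  differences into the consensus pair (visible as a small upward bias in
  per-gene dS at very low divergence).
* The two-cluster model assumes a single stratum per region; a region
  spanning strata of very different ages may fail the separation criterion
  and be rejected rather than split.
* Hard-filtered sites are lost to all downstream stages: in particular, an
  ORF-disrupting variant removed by the depth-spike rule (which trims ~2% of
  sites at 20× Poisson depth) leaves that neo-Y copy looking functional, so
  end-to-end degeneration estimates are bounded by filter sensitivity.
* The rearrangement scheme resolves only simple, non-nested events.
* Read-alignment mismatch tiers (unfiltered / ≤2 / 0 mismatches) are
  accepted as alternative coverage tracks if supplied but are not produced
  here, since read processing is out of scope.
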