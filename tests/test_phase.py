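import numpy as np
import pytest

from neoxy.io import GenomicInterval, Genotype, VariantRecord
from neoxy.phase import (
    FilterParams,
    GametologAssignment,
    HaplotypeMatrix,
    build_haplotype_matrix,
    cluster_haplotypes,
    extract_gametolog_pairs,
    filter_variants,
    regenotype_haploid,
    HaploidPanel,
)
from neoxy.scan import SexLinkedRegion


def _rec(start, qual, gts, dps, chrom="c1", ref="A", alts=("T",)):
    gqs = [99] * len(gts)
    return VariantRecord(chrom, start, ref, alts, qual, list(gts), list(dps), gqs)


HET = Genotype((0, 1), True)
HOM_ALT = Genotype((1, 1), True)
HOM_REF = Genotype((0, 0), True)


def _cascade_records():
    """Twelve records exercising every rule of the filter cascade.

    Records passing rules 1-3 have depths averaging 20 (mean genotype depth
    = 20), so rule 4 rejects het sites with QUAL < 40 and rule 5 rejects
    sites with any genotype depth > 20 + 3*sqrt(20) ~ 33.4.
    """
    mask = (GenomicInterval("c1", 1000, 1100),)
    records = [
        _rec(10, 25.0, [HOM_ALT, HOM_ALT], [20, 20]),    # 0: QUAL 25 < 30
        _rec(20, 80.0, [HOM_ALT, HOM_ALT], [1, 1]),      # 1: site depth 2 < 3
        _rec(30, 100.0, [HET, HOM_REF], [3, 20]),        # 2: het with DP 3 < 4
        _rec(40, 45.0, [HOM_ALT, HOM_ALT], [3, 20]),     # 3: hom QUAL 45 & DP 3
        _rec(50, 39.0, [HET, HET], [20, 20]),            # 4: het QUAL 39 < 2*20
        _rec(60, 120.0, [HOM_ALT, HET], [36, 4]),        # 5: depth 36 > 33.4
        _rec(1050, 90.0, [HOM_ALT, HOM_ALT], [20, 20]),  # 6: inside repeat mask
        _rec(70, 60.0, [HOM_ALT, HOM_ALT], [20, 20]),    # 7: passes
        _rec(80, 95.0, [HET, HOM_REF], [20, 20]),        # 8: passes
        _rec(90, 41.0, [HET, HET], [20, 20]),            # 9: passes (QUAL > 40)
        _rec(100, 55.0, [HOM_ALT, HOM_REF], [20, 20]),   # 10: passes
        _rec(110, 200.0, [HET, HET], [20, 20]),          # 11: passes
    ]
    expected_tags = {
        10: "low_qual_or_site_depth",
        20: "low_qual_or_site_depth",
        30: "het_low_depth",
        40: "hom_low_qual_depth",
        50: "het_qual_below_depth_factor",
        60: "depth_spike",
        1050: "repeat_overlap",
    }
    return records, FilterParams(repeat_mask=mask), expected_tags


class TestFilterCascade:
    def test_expected_partition_and_rule_tags(self):
        records, params, expected = _cascade_records()
        kept, removed = filter_variants(records, params)
        assert {r.start for r in kept} == {70, 80, 90, 100, 110}
        assert {r.start: tag for r, tag in removed} == expected

    def test_first_violated_rule_wins(self):
        # QUAL 25 and het depth 3: rule 1 fires before rule 2
        rec = _rec(5, 25.0, [HET, HOM_REF], [3, 20])
        _, removed = filter_variants([rec] + _cascade_records()[0])
        assert dict((r.start, t) for r, t in removed)[5] == "low_qual_or_site_depth"

    def test_order_independence(self):
        records, params, _ = _cascade_records()
        kept1, _ = filter_variants(records, params)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(records)
            rng.shuffle(shuffled)
            kept2, _ = filter_variants(shuffled, params)
            assert {id(r) for r in kept1} == {id(r) for r in kept2}

    def test_no_depth_anywhere_rejected(self):
        rec = _rec(10, 60.0, [HOM_ALT], [None])
        with pytest.raises(ValueError, match="DP"):
            filter_variants([rec])


def _matrix(haps, sexes, positions=None, chrom="c1"):
    """Build a HaplotypeMatrix from a (2*n_samples, n_sites) allele array."""
    haps = np.asarray(haps, dtype=np.int8)
    samples = list(sexes)
    if positions is None:
        positions = np.arange(haps.shape[1], dtype=np.int64)
    region = GenomicInterval(chrom, 0, int(positions[-1]) + 1)
    labels = [(s, h) for s in samples for h in (0, 1)]
    return HaplotypeMatrix(region, np.asarray(positions), haps, labels, dict(sexes))


def _divergent_haps(n_males, n_females, n_sites, y_rows, rng, poly=0.02):
    """Y haplotypes carry the alt allele at every site; others carry noise."""
    n_haps = 2 * (n_males + n_females)
    h = (rng.random((n_haps, n_sites)) < poly).astype(np.int8)
    for r in y_rows:
        h[r] = 1
    return h


class TestClusterHaplotypes:
    SEXES = {"M1": "M", "M2": "M", "M3": "M", "F1": "F", "F2": "F"}

    def test_assigns_y_cluster_correctly(self):
        rng = np.random.default_rng(0)
        # males' Y haplotypes on rows 1 (M1 hap 1), 2 (M2 hap 0), 5 (M3 hap 1)
        h = _divergent_haps(3, 2, 60, [1, 2, 5], rng)
        a = cluster_haplotypes(_matrix(h, self.SEXES))
        assert a.status == "assigned"
        assert a.y_haplotype == {"M1": 1, "M2": 0, "M3": 1}
        assert a.separation >= 3.0

    def test_no_divergence_rejected(self):
        h = np.zeros((10, 40), dtype=np.int8)
        a = cluster_haplotypes(_matrix(h, self.SEXES))
        assert a.status == "rejected"

    def test_female_haplotype_in_y_cluster_is_ambiguous(self):
        rng = np.random.default_rng(1)
        # female F1 hap 0 (row 6) also carries the divergent haplotype
        h = _divergent_haps(3, 2, 60, [1, 2, 5, 6], rng)
        a = cluster_haplotypes(_matrix(h, self.SEXES))
        assert a.status == "ambiguous"

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        h = _divergent_haps(3, 2, 60, [1, 2, 5], rng)
        a = cluster_haplotypes(_matrix(h, self.SEXES))
        order = ["M3", "M1", "F2", "M2", "F1"]
        perm = {s: self.SEXES[s] for s in order}
        rows = []
        for s in order:
            i = list(self.SEXES).index(s)
            rows += [h[2 * i], h[2 * i + 1]]
        b = cluster_haplotypes(_matrix(np.array(rows), perm))
        assert b.status == "assigned" and b.y_haplotype == a.y_haplotype

    def test_haplotype_swap_invariance(self):
        rng = np.random.default_rng(3)
        h = _divergent_haps(3, 2, 60, [1, 2, 5], rng)
        swapped = h.copy()
        swapped[[0, 1]] = swapped[[1, 0]]  # swap M1's two haplotypes
        a = cluster_haplotypes(_matrix(swapped, self.SEXES))
        assert a.status == "assigned"
        assert a.y_haplotype == {"M1": 0, "M2": 0, "M3": 1}

    def test_too_few_sites_rejected(self):
        h = np.zeros((10, 5), dtype=np.int8)
        a = cluster_haplotypes(_matrix(h, self.SEXES), min_sites=20)
        assert a.status == "rejected"

    def test_unphased_male_het_rejected_at_matrix_build(self):
        rec = _rec(10, 60.0, [Genotype((0, 1), phased=False), HOM_REF], [20, 20])
        with pytest.raises(ValueError, match="unphased"):
            build_haplotype_matrix([rec], ["M1", "F1"], {"M1": "M", "F1": "F"},
                                   GenomicInterval("c1", 0, 100))

    def test_simulated_stratum_recovers_truth(self, small_bundle):
        """On simulated data the Y choice matches the generator's labels."""
        b = small_bundle
        kept, _ = filter_variants(b.variants)
        region = GenomicInterval(b.config.neox_chrom, *b.config.stratum)
        m = build_haplotype_matrix(kept, b.samples, b.sexes, region)
        a = cluster_haplotypes(m)
        assert a.status == "assigned"
        assert a.y_haplotype == b.male_y_hap


class TestRegenotype:
    SAMPLES = ["M1", "F1"]
    SEXES = {"M1": "M", "F1": "F"}

    def _assignment(self, y_idx):
        return GametologAssignment(
            GenomicInterval("c1", 0, 1000), "assigned", {"M1": y_idx}, 10.0, 50)

    def test_het_maps_to_x_and_y_calls(self):
        rec = _rec(10, 60.0, [HET, HOM_REF], [20, 20])
        xp, yp = regenotype_haploid(self._assignment(1), [rec],
                                    self.SAMPLES, self.SEXES)
        assert xp.records[0].genotypes[0].alleles == (0,)   # M1 X call
        assert yp.records[0].genotypes[0].alleles == (1,)   # M1 Y call
        assert xp.samples == ["M1_X", "F1_h1", "F1_h2"]

    def test_hom_maps_to_same_allele_on_both(self):
        rec = _rec(10, 60.0, [HOM_ALT, HOM_REF], [20, 20])
        xp, yp = regenotype_haploid(self._assignment(0), [rec],
                                    self.SAMPLES, self.SEXES)
        assert xp.records[0].genotypes[0].alleles == (1,)
        assert yp.records[0].genotypes[0].alleles == (1,)

    def test_missing_stays_missing(self):
        rec = _rec(10, 60.0, [Genotype((None, None)), HOM_REF], [None, 20])
        xp, yp = regenotype_haploid(self._assignment(1), [rec],
                                    self.SAMPLES, self.SEXES)
        assert xp.records[0].genotypes[0].alleles == (None,)
        assert yp.records[0].genotypes[0].alleles == (None,)

    def test_unassigned_region_rejected(self):
        a = GametologAssignment(GenomicInterval("c1", 0, 10), "rejected")
        with pytest.raises(ValueError, match="assigned"):
            regenotype_haploid(a, [], self.SAMPLES, self.SEXES)

    def test_y_calls_match_simulated_haplotype(self, small_bundle):
        """Round-trip: haploid Y calls equal the generator's Y haplotype at
        every filtered site in the stratum."""
        b = small_bundle
        kept, _ = filter_variants(b.variants)
        region = GenomicInterval(b.config.neox_chrom, *b.config.stratum)
        m = build_haplotype_matrix(kept, b.samples, b.sexes, region)
        a = cluster_haplotypes(m)
        xp, yp = regenotype_haploid(a, kept, b.samples, b.sexes)
        males = [s for s in b.samples if b.sexes[s] == "M"]
        s_index = {s: i for i, s in enumerate(b.samples)}
        in_region = [r for r in kept
                     if region.start <= r.start < region.end]
        assert len(in_region) == len(yp.records)
        for rec, yrec in zip(in_region, yp.records):
            for mi, male in enumerate(males):
                truth = rec.genotypes[s_index[male]].alleles[b.male_y_hap[male]]
                assert yrec.genotypes[mi].alleles[0] == truth


def _panel(samples, records):
    return HaploidPanel(samples, records)


def _haploid_rec(start, alleles, ref="A", alts=("T",), chrom="c1"):
    gts = [Genotype((a,)) for a in alleles]
    return VariantRecord(chrom, start, ref, alts, 60.0, gts,
                         [20] * len(gts), [99] * len(gts))


class TestExtractPairs:
    REF = {"c1": "ATGAAACCCGGGTTTTAA" + "ACGT" * 20}
    GENE_KW = dict()

    def _genes(self, strand="+"):
        from neoxy.io import GeneModel
        return [GeneModel("g1", "c1", strand, ((0, 18),), (0,))]

    def _regions(self, start=0, end=100):
        return [SexLinkedRegion(GenomicInterval("c1", start, end),
                                "heterogametic", 5, 1.0, 0.01)]

    def test_no_differences_identical_sequences(self):
        xp = _panel(["M1_X"], [])
        yp = _panel(["M1_Y"], [])
        (p,) = extract_gametolog_pairs(xp, yp, self.REF, self._genes(),
                                       self._regions())
        assert p.x_seq == p.y_seq == self.REF["c1"][:18]
        assert p.assignment == "sex-linked"

    def test_substituted_codon_changes_only_those_positions(self):
        yp = _panel(["M1_Y", "M2_Y"], [_haploid_rec(4, [1, 1])])
        xp = _panel(["M1_X"], [])
        (p,) = extract_gametolog_pairs(xp, yp, self.REF, self._genes(),
                                       self._regions())
        assert p.x_seq == self.REF["c1"][:18]
        assert p.y_seq == self.REF["c1"][:4] + "T" + self.REF["c1"][5:18]

    def test_indel_allele_applied(self):
        # 2 bp deletion: REF "AA" at 3 -> "A"
        yp = _panel(["M1_Y"], [_haploid_rec(3, [1], ref="AAA", alts=("A",))])
        xp = _panel(["M1_X"], [])
        (p,) = extract_gametolog_pairs(xp, yp, self.REF, self._genes(),
                                       self._regions())
        assert len(p.y_seq) == 16
        assert p.y_seq == self.REF["c1"][:4] + self.REF["c1"][6:18]

    def test_minus_strand_gene_reported_in_coding_orientation(self):
        from neoxy.io import GeneModel

        # place reverse-complemented ORF on the genome
        ref = {"c1": "TTACCCGGGTTTCAT" + "ACGT" * 10}
        genes = [GeneModel("g1", "c1", "-", ((0, 15),), (0,))]
        xp = _panel(["M1_X"], [])
        yp = _panel(["M1_Y"], [])
        (p,) = extract_gametolog_pairs(xp, yp, ref, genes, self._regions())
        assert p.x_seq == "ATGAAACCCGGGTAA"

    def test_majority_rules_consensus_with_ref_ties(self):
        yp = _panel(["M1_Y", "M2_Y", "M3_Y", "M4_Y"],
                    [_haploid_rec(4, [1, 1, 1, 0]),   # 3:1 alt -> alt
                     _haploid_rec(8, [1, 1, 0, 0])])  # tie -> ref
        xp = _panel(["M1_X"], [])
        (p,) = extract_gametolog_pairs(xp, yp, self.REF, self._genes(),
                                       self._regions())
        assert p.y_seq[4] == "T" and p.y_seq[8] == self.REF["c1"][8]

    def test_boundary_spanning_gene_goes_to_par_with_warning(self):
        with pytest.warns(UserWarning, match="straddles"):
            (p,) = extract_gametolog_pairs(
                _panel(["M1_X"], []), _panel(["M1_Y"], []), self.REF,
                self._genes(), self._regions(start=0, end=9))
        assert p.assignment == "PAR"

    def test_gene_outside_regions_is_par(self):
        (p,) = extract_gametolog_pairs(
            _panel(["M1_X"], []), _panel(["M1_Y"], []), self.REF,
            self._genes(), self._regions(start=50, end=90))
        assert p.assignment == "PAR"

    def test_simulated_stratum_gene_pair_count(self, small_bundle):
        b = small_bundle
        kept, _ = filter_variants(b.variants)
        region = GenomicInterval(b.config.neox_chrom, *b.config.stratum)
        m = build_haplotype_matrix(kept, b.samples, b.sexes, region)
        a = cluster_haplotypes(m)
        xp, yp = regenotype_haploid(a, kept, b.samples, b.sexes)
        regions = [SexLinkedRegion(region, "heterogametic", 10, 1.0, 0.01)]
        pairs = extract_gametolog_pairs(xp, yp, b.reference, b.genes, regions)
        n_stratum = sum(1 for g in b.genes
                        if region.contains(g.span))
        assert sum(1 for p in pairs if p.assignment == "sex-linked") == n_stratum
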