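import itertools
import warnings

import numpy as np
import pytest

from neoxy.dnds import (
    CodonAlignment,
    align_codons,
    alignment_score,
    filter_pairs,
    jukes_cantor,
    ng86,
    summarize_regions,
    welch_t,
    DnDsResult,
    _aa,
)
from neoxy.simulate import simulate_synonymous_pair

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def _random_codons(rng, n, allow_stop=False):
    out = []
    while len(out) < n:
        c = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if allow_stop or c not in STOPS:
            out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_align_score(x, y, match=2, mismatch=-1, gap=-4):
    """Exhaustive enumeration of all codon alignments (small inputs only)."""
    cx = [x[i:i + 3] for i in range(0, len(x), 3)]
    cy = [y[i:i + 3] for i in range(0, len(y), 3)]

    def rec(i, j):
        if i == len(cx):
            return gap * (len(cy) - j)
        if j == len(cy):
            return gap * (len(cx) - i)
        aa_i, aa_j = _aa(cx[i]), _aa(cy[j])
        sub = match if (aa_i == aa_j and aa_i != "X") else mismatch
        return max(rec(i + 1, j + 1) + sub, rec(i + 1, j) + gap,
                   rec(i, j + 1) + gap)

    return rec(0, 0)


def brute_force_path_counts(cx, cy):
    """Average syn/nonsyn differences over stop-free minimal mutation paths."""
    diff = [p for p in range(3) if cx[p] != cy[p]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = cx, 0, 0, True
        for p in order:
            nxt = cur[:p] + cy[p] + cur[p + 1:]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return None
    return (float(np.mean([r[0] for r in results])),
            float(np.mean([r[1] for r in results])))


def brute_force_syn_sites(codon):
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                n = codon[:pos] + b + codon[pos + 1:]
                if _aa(n) == aa and _aa(n) != "*":
                    s += 1 / 3
    return s


class TestAlignCodons:
    def test_identical_sequences_align_gapless(self):
        x = "ATGAAACCCGGG"
        a = align_codons((x, x))
        assert a.x_aligned == a.y_aligned == x
        assert a.comparable == [0, 1, 2, 3]

    def test_single_codon_deletion_gives_one_triplet_gap(self):
        x = "ATGAAACCCGGGTTC"
        y = x[:6] + x[9:]  # drop codon 2
        a = align_codons((x, y))
        assert a.y_aligned.count("-") == 3
        assert "---" in a.y_aligned
        assert a.x_aligned == x

    def test_score_matches_exhaustive_enumeration(self):
        """DP score equals brute-force enumeration over all codon alignments."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            nx, ny = rng.integers(1, 7), rng.integers(1, 7)
            x = _random_codons(rng, nx, allow_stop=True)
            y = _random_codons(rng, ny, allow_stop=True)
            aln = align_codons((x, y))
            assert alignment_score(aln) == brute_force_align_score(x, y)

    def test_stop_and_gap_columns_not_comparable(self):
        a = align_codons(("ATGTAACCC", "ATGTAACCC"))
        assert a.comparable == [0, 2]  # TAA is a stop

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_codons(("", "ATG"))

    def test_non_triplet_x_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            align_codons(("ATGA", "ATG"))


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        r = ng86(align_codons(("ATGAAACCC", "ATGAAACCC")))
        assert (r.Nd, r.Sd, r.dN, r.dS) == (0, 0, 0, 0)
        assert "dS_zero" in r.flags

    def test_phe_codon_example(self):
        """TTT vs TTC: one synonymous difference; S = 1/3 per codon."""
        r = ng86(CodonAlignment("TTT", "TTC", [0]))
        assert r.Nd == 0 and r.Sd == 1
        assert r.S == pytest.approx(1 / 3)
        assert r.N == pytest.approx(8 / 3)

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(1)
        x = _random_codons(rng, 50)
        y = _random_codons(rng, 50)
        a = CodonAlignment(x, y, list(range(50)))
        r = ng86(a)
        assert r.N + r.S == pytest.approx(3 * r.n_codons)

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert np.isnan(jukes_cantor(0.75))

    def test_symmetry_under_sequence_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = _random_codons(rng, 30)
            y = _random_codons(rng, 30)
            a = ng86(CodonAlignment(x, y, list(range(30))))
            b = ng86(CodonAlignment(y, x, list(range(30))))
            for attr in ("N", "S", "Nd", "Sd", "dN", "dS"):
                va, vb = getattr(a, attr), getattr(b, attr)
                assert va == pytest.approx(vb, nan_ok=True)

    def test_concatenation_additivity(self):
        """Site/difference counts on concatenated genes equal per-gene sums."""
        rng = np.random.default_rng(3)
        xs = [_random_codons(rng, 20) for _ in range(3)]
        ys = [_random_codons(rng, 20) for _ in range(3)]
        parts = [ng86(CodonAlignment(x, y, list(range(20))))
                 for x, y in zip(xs, ys)]
        whole = ng86(CodonAlignment("".join(xs), "".join(ys), list(range(60))))
        assert whole.N == pytest.approx(sum(p.N for p in parts))
        assert whole.S == pytest.approx(sum(p.S for p in parts))
        assert whole.Nd == pytest.approx(sum(p.Nd for p in parts))
        assert whole.Sd == pytest.approx(sum(p.Sd for p in parts))

    def test_counts_match_path_enumeration(self):
        """Nd/Sd and site counts agree with exhaustive enumeration on random
        codon pairs."""
        from neoxy.dnds import _path_counts, _syn_sites

        rng = np.random.default_rng(4)
        for _ in range(300):
            cx = _random_codons(rng, 1)
            cy = _random_codons(rng, 1)
            assert _path_counts(cx, cy) == brute_force_path_counts(cx, cy)
            assert _syn_sites(cx) == pytest.approx(brute_force_syn_sites(cx))

    def test_agrees_with_biopython_reference(self):
        """Cross-check dN/dS against Biopython's independent NG86 routine."""
        import warnings as w

        from Bio import BiopythonWarning
        from Bio.Align import MultipleSeqAlignment, SeqRecord
        from Bio.Seq import Seq

        with w.catch_warnings():
            w.simplefilter("ignore")
            from Bio import codonalign
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

            rng = np.random.default_rng(5)
            x, y = simulate_synonymous_pair(200, 0.3, rng)
            mine = ng86(CodonAlignment(x, y, list(range(200))))
            dn, ds = cal_dn_ds(CodonSeq(x), CodonSeq(y), method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-4)
            assert mine.dS == pytest.approx(ds, abs=1e-4)

    def test_ds_recovers_generating_synonymous_divergence(self):
        """Mean dS over replicates sits within 3 SE of the true distance."""
        d_true = 0.3
        estimates = []
        for seed in range(30):
            x, y = simulate_synonymous_pair(300, d_true, seed)
            r = ng86(align_codons((x, y)))
            estimates.append(r.dS)
        est = np.array(estimates)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - d_true) < 3 * se


def _result(ds, omega, flags=("ok",)):
    return DnDsResult("g", 100, 200.0, 100.0, 10.0, 5.0, 0.05, 0.05,
                      ds * omega, ds, omega, flags)


class TestFilterPairs:
    def test_saturated_ds_excluded(self):
        assert filter_pairs([_result(2.5, 1.0)]) == []

    def test_saturated_omega_excluded(self):
        assert filter_pairs([_result(1.0, 10.5)]) == []

    def test_normal_pair_retained(self):
        assert len(filter_pairs([_result(0.5, 1.0)])) == 1

    def test_ds_zero_retained_for_ds_summaries(self):
        r = DnDsResult("g", 100, 200.0, 100.0, 3.0, 0.0, 0.015, 0.0,
                       0.015, 0.0, float("nan"), ("dS_zero",))
        assert len(filter_pairs([r])) == 1

    def test_jc_undefined_dropped(self):
        r = DnDsResult("g", 100, 200.0, 100.0, 3.0, 90.0, 0.015, 0.9,
                       0.015, float("nan"), float("nan"), ("jc_undefined",))
        assert filter_pairs([r]) == []


class TestSummaries:
    def test_identical_groups_give_t_zero_p_one(self):
        t = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t.statistic == pytest.approx(0.0)
        assert t.pvalue == pytest.approx(1.0)

    def test_textbook_welch_values(self):
        """{1,2,3} vs {2,3,4}: equal variances 1, t = -1/sqrt(2/3), df = 4."""
        t = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t.statistic == pytest.approx(-1.0 / np.sqrt(2 / 3))
        assert t.df == pytest.approx(4.0)

    def test_median_reporting_and_test(self):
        a = [_result(ds, 1.0) for ds in (0.1, 0.2, 0.3)]
        b = [_result(ds, 2.0) for ds in (0.5, 0.6, 0.7)]
        summaries, tests = summarize_regions({"A": a, "B": b})
        med = {s.region: s.median_ds for s in summaries}
        assert med == {"A": pytest.approx(0.2), "B": pytest.approx(0.6)}
        assert tests["dS"].pvalue < 0.05

    def test_single_pair_region_skips_test(self):
        with pytest.warns(UserWarning, match="too few"):
            _, tests = summarize_regions({
                "A": [_result(0.1, 1.0)],
                "B": [_result(0.5, 1.0), _result(0.6, 1.0)],
            })
        assert tests == {}

    def test_power_to_separate_divergence_levels(self):
        """Two strata simulated at synonymous divergence 0.005 vs 0.02 are
        separated at alpha = 0.01 in nearly all replicate cohorts."""
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = [ng86(align_codons(simulate_synonymous_pair(300, 0.005, rng)))
                 for _ in range(30)]
            b = [ng86(align_codons(simulate_synonymous_pair(300, 0.02, rng)))
                 for _ in range(30)]
            _, tests = summarize_regions(
                {"young": filter_pairs(a), "old": filter_pairs(b)})
            rejections += tests["dS"].pvalue < 0.01
        assert rejections >= int(0.9 * n_rep)
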