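"""Codon-aware gametolog alignment and Nei-Gojobori (1986) dN/dS.

Synonymous (S) and nonsynonymous (N) site counts follow the NG86 convention:
each codon position contributes (number of synonymous single-nucleotide
neighbours)/3 synonymous sites, so N + S = 3 per codon; changes to stop
codons count as nonsynonymous. Differences in multi-substitution codons are
averaged over all orderings of the minimal mutation paths, excluding paths
that pass through a stop codon. Proportions are corrected for multiple hits
with the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3), and omega = dN/dS.

Pairs with dS >= 2 or omega >= 10 are conventionally discarded as saturated:
at that divergence the correction is unreliable and estimates explode.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .phase import GametologPair

BASES = "ACGT"

_CODON_AA: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_AA:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_AA.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_AA[stop] = "*"
    return _CODON_AA.get(codon, "X")


# ---------------------------------------------------------------------------
# codon-level global alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Equal-length gapped X/Y sequences with gaps in whole-codon units."""

    x_aligned: str
    y_aligned: str
    comparable: list[int] = field(default_factory=list)  # codon column indices

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.x_aligned[3 * i:3 * i + 3], self.y_aligned[3 * i:3 * i + 3])
            for i in self.comparable
        ]


def _is_comparable(cx: str, cy: str) -> bool:
    if "-" in cx or "-" in cy:
        return False
    if any(b not in BASES for b in cx + cy):
        return False
    if _aa(cx) == "*" or _aa(cy) == "*":
        return False
    return True


def align_codons(
    pair: GametologPair | tuple[str, str],
    match: int = 2,
    mismatch: int = -1,
    gap: int = -4,
) -> CodonAlignment:
    """Global Needleman-Wunsch alignment over codon units.

    Codons score ``match`` when they encode the same amino acid and
    ``mismatch`` otherwise; each codon gap costs ``gap``. Traceback ties are
    broken deterministically: diagonal, then up (gap in Y), then left.
    A trailing partial codon on the Y side is trimmed before alignment.
    """
    if isinstance(pair, GametologPair):
        x, y = pair.x_seq, pair.y_seq
    else:
        x, y = pair
    if not x or not y:
        raise ValueError("cannot align an empty sequence")
    if len(x) < 3 or len(y) < 3:
        raise ValueError("sequences must be at least one codon long")
    if len(x) % 3:
        raise ValueError("X sequence length must be divisible by 3")
    y = y[: len(y) - len(y) % 3]
    cx = [x[i:i + 3] for i in range(0, len(x), 3)]
    cy = [y[i:i + 3] for i in range(0, len(y), 3)]
    n, m = len(cx), len(cy)

    # amino-acid identity scoring, vectorized; 'X' (ambiguity) never matches
    aa_x = [_aa(c) for c in cx]
    aa_y = [_aa(c) for c in cy]
    aa_codes = {a: k for k, a in enumerate(dict.fromkeys(aa_x + aa_y + ["X"]))}
    ax = np.array([aa_codes[a] for a in aa_x])
    ay = np.array([aa_codes[a] for a in aa_y])
    same = (ax[:, None] == ay[None, :]) & (ax[:, None] != aa_codes["X"])
    sub = np.where(same, match, mismatch).astype(np.int64)

    # row-wise DP; the in-row gap recurrence row[j] = max(c[j], row[j-1]+gap)
    # unrolls to a running maximum of c[k] - gap*k (max-plus scan)
    S = np.zeros((n + 1, m + 1), dtype=np.int64)
    S[:, 0] = gap * np.arange(n + 1)
    S[0, :] = gap * np.arange(m + 1)
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        diag = S[i - 1, :-1] + sub[i - 1]
        up = S[i - 1, 1:] + gap
        c = np.maximum(diag, up)
        vals = np.concatenate(([np.int64(S[i, 0])], c - gap * j_idx))
        S[i, 1:] = gap * j_idx + np.maximum.accumulate(vals)[1:]
    xa: list[str] = []
    ya: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + sub[i - 1, j - 1]:
            xa.append(cx[i - 1])
            ya.append(cy[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + gap:
            xa.append(cx[i - 1])
            ya.append("---")
            i -= 1
        else:
            xa.append("---")
            ya.append(cy[j - 1])
            j -= 1
    xs = "".join(reversed(xa))
    ys = "".join(reversed(ya))
    comparable = [
        k for k in range(len(xs) // 3)
        if _is_comparable(xs[3 * k:3 * k + 3], ys[3 * k:3 * k + 3])
    ]
    return CodonAlignment(xs, ys, comparable)


def alignment_score(aln: CodonAlignment, match: int = 2, mismatch: int = -1,
                    gap: int = -4) -> int:
    """Score of an existing codon alignment under the align_codons scheme."""
    total = 0
    for k in range(len(aln.x_aligned) // 3):
        a = aln.x_aligned[3 * k:3 * k + 3]
        b = aln.y_aligned[3 * k:3 * k + 3]
        if a == "---" or b == "---":
            total += gap
        else:
            aa_a, aa_b = _aa(a), _aa(b)
            total += match if (aa_a == aa_b and aa_a != "X") else mismatch
    return total


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    """NG86 counts and Jukes-Cantor-corrected rates for one gametolog pair."""

    gene_id: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float
    flags: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of one codon: sum over positions of
    (synonymous single-nucleotide neighbours)/3. Stops are not synonymous."""
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1:]
            if _aa(neighbour) == aa and _aa(neighbour) != "*":
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _path_counts(cx: str, cy: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences averaged over minimal mutation paths.

    Paths visiting a stop codon are excluded; ``None`` when every ordering
    passes through a stop.
    """
    diff_pos = [p for p in range(3) if cx[p] != cy[p]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_sum = 0.0
    non_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = cx
        syn = non = 0
        ok = True
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
            syn_sum += syn
            non_sum += non
            n_paths += 1
    if n_paths == 0:
        return None
    return (syn_sum / n_paths, non_sum / n_paths)


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment, gene_id: str = "") -> DnDsResult:
    """Nei-Gojobori site/difference counts with Jukes-Cantor correction."""
    pairs = alignment.codon_pairs()
    if not pairs:
        raise ValueError("no comparable codons in alignment")
    flags: list[str] = []
    N = S = Nd = Sd = 0.0
    n_used = 0
    for cx, cy in pairs:
        counts = _path_counts(cx, cy)
        if counts is None:
            flags.append("path_stop_skipped")
            continue
        sd, nd = counts
        s_sites = (_syn_sites(cx) + _syn_sites(cy)) / 2.0
        S += s_sites
        N += 3.0 - s_sites
        Sd += sd
        Nd += nd
        n_used += 1
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    if np.isnan(dN) or np.isnan(dS):
        flags.append("jc_undefined")
    omega = float("nan")
    if not np.isnan(dS):
        if dS == 0.0:
            flags.append("dS_zero")
        elif not np.isnan(dN):
            omega = dN / dS
    if not flags:
        flags.append("ok")
    return DnDsResult(
        gene_id=gene_id, n_codons=n_used, N=N, S=S, Nd=Nd, Sd=Sd,
        pN=pN, pS=pS, dN=dN, dS=dS, omega=omega, flags=tuple(dict.fromkeys(flags)),
    )


def ng86_pair(pair: GametologPair) -> DnDsResult:
    """Convenience: align a gametolog pair and run NG86."""
    return ng86(align_codons(pair), gene_id=pair.gene_id)


# ---------------------------------------------------------------------------
# saturation filter and regional summaries
# ---------------------------------------------------------------------------

def filter_pairs(
    results: list[DnDsResult], max_ds: float = 2.0, max_omega: float = 10.0
) -> list[DnDsResult]:
    """Retain pairs below the saturation thresholds (dS < 2, omega < 10).

    Pairs with dS = 0 are retained (usable for dS summaries) but their
    undefined omega is excluded from omega summaries downstream; pairs with
    an undefined Jukes-Cantor correction are dropped.
    """
    kept = []
    for r in results:
        if "jc_undefined" in r.flags:
            continue
        if not (r.dS < max_ds):
            continue
        if "dS_zero" not in r.flags and not (r.omega < max_omega):
            continue
        kept.append(r)
    return kept


@dataclass
class RegionDivergenceSummary:
    region: str
    n_pairs: int
    median_ds: float
    median_omega: float


@dataclass
class WelchTest:
    statistic: float
    df: float
    pvalue: float


def welch_t(a: np.ndarray, b: np.ndarray) -> WelchTest:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchTest(float(res.statistic), float(res.df), float(res.pvalue))


def summarize_regions(
    results_by_region: dict[str, list[DnDsResult]]
) -> tuple[list[RegionDivergenceSummary], dict[str, WelchTest]]:
    """Median dS and omega per region plus Welch tests between two regions.

    The tests (on dS and, separately, on omega over pairs with defined
    omega) are computed only when exactly two regions each retain >= 2 pairs.
    """
    summaries = []
    for region, results in results_by_region.items():
        ds = np.array([r.dS for r in results if not np.isnan(r.dS)])
        om = np.array([r.omega for r in results if not np.isnan(r.omega)])
        summaries.append(RegionDivergenceSummary(
            region=region,
            n_pairs=len(results),
            median_ds=float(np.median(ds)) if len(ds) else float("nan"),
            median_omega=float(np.median(om)) if len(om) else float("nan"),
        ))
    tests: dict[str, WelchTest] = {}
    if len(results_by_region) == 2:
        (ra, rsa), (rb, rsb) = results_by_region.items()
        for name, extract in (
            ("dS", lambda r: r.dS),
            ("omega", lambda r: r.omega),
        ):
            a = np.array([extract(r) for r in rsa if not np.isnan(extract(r))])
            b = np.array([extract(r) for r in rsb if not np.isnan(extract(r))])
            if len(a) >= 2 and len(b) >= 2:
                tests[name] = welch_t(a, b)
            else:
                warnings.warn(f"too few pairs for the {name} test; skipped")
    return summaries, tests
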