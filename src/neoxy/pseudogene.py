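"""ORF-integrity classification of neo-Y gene copies.

A gene copy is nonfunctional when its ORF is disrupted relative to the
annotated parent CDS: a frameshifting indel (net gap length not a multiple of
3) or a premature stop codon read in the frame implied by upstream indels.
The fraction of nonfunctional copies summarizes degeneration per region.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from scipy.stats import binomtest

from .dnds import CodonAlignment, _aa, align_codons

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfDisruption:
    """One ORF-breaking event, positioned in the parent CDS frame."""

    kind: str  # premature_stop | frameshift
    position: int  # 0-based offset in the parent CDS
    detail: str  # stop codon, or net gap length mod 3


@dataclass
class PseudogeneCall:
    gene_id: str
    status: str  # functional | nonfunctional
    disruptions: tuple[OrfDisruption, ...] = ()


def _nucleotide_alignment(candidate: str, parent: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(parent, candidate)[0]
    return str(aln[0]), str(aln[1])


def _gapped_pair(candidate: str, parent: str,
                 alignment: CodonAlignment | None) -> tuple[str, str]:
    """(parent_aligned, candidate_aligned); codon-level when frames allow."""
    if alignment is not None:
        return alignment.x_aligned, alignment.y_aligned
    if len(candidate) % 3 == 0 and len(parent) % 3 == 0:
        aln = align_codons((parent, candidate))
        return aln.x_aligned, aln.y_aligned
    return _nucleotide_alignment(candidate, parent)


def detect_disruptions(
    candidate: str,
    parent: str,
    alignment: CodonAlignment | None = None,
) -> list[OrfDisruption]:
    """Find frameshifts and premature stops in ``candidate`` vs ``parent``.

    Frameshift: scanning aligned columns 5'->3', a maximal gap run after
    which the cumulative candidate-vs-parent length offset leaves frame
    (offset mod 3 != 0). A later compensating gap restores the frame but the
    original event still counts: the intervening peptide is garbled.

    Premature stop: any stop codon read in the candidate's own running frame
    (which is exactly the frame implied by upstream cumulative gaps) whose
    aligned parent position is strictly before the parent's terminal codon.
    """
    if len(candidate) < 3:
        raise ValueError("candidate shorter than one codon")
    pa, ca = _gapped_pair(candidate, parent, alignment)
    disruptions: list[OrfDisruption] = []

    # --- frameshifts from cumulative gap offset ---------------------------
    offset = 0  # candidate length minus parent length, so far
    parent_pos = 0
    in_gap = False
    last_frame_ok = True
    for col in range(len(pa)):
        p_gap = pa[col] == "-"
        c_gap = ca[col] == "-"
        if p_gap or c_gap:
            offset += 1 if p_gap else -1
            in_gap = True
        else:
            if in_gap:
                if last_frame_ok and offset % 3 != 0:
                    disruptions.append(OrfDisruption(
                        "frameshift", parent_pos, f"shift={offset % 3}"
                    ))
                last_frame_ok = offset % 3 == 0
                in_gap = False
        if not p_gap:
            parent_pos += 1
    if in_gap and last_frame_ok and offset % 3 != 0:
        disruptions.append(OrfDisruption("frameshift", parent_pos, f"shift={offset % 3}"))

    # --- premature stops in the candidate's running frame -----------------
    cand_to_parent: list[int] = []
    parent_pos = 0
    for col in range(len(pa)):
        if ca[col] != "-":
            cand_to_parent.append(parent_pos)
        if pa[col] != "-":
            parent_pos += 1
    terminal_codon_start = len(parent) - 3
    cand_ungapped = ca.replace("-", "")
    for i in range(0, len(cand_ungapped) - 2, 3):
        codon = cand_ungapped[i:i + 3]
        if _aa(codon) == "*":
            p_pos = cand_to_parent[i]
            if p_pos < terminal_codon_start:
                disruptions.append(OrfDisruption("premature_stop", p_pos, codon))
    disruptions.sort(key=lambda d: d.position)
    return disruptions


def classify_gene(gene_id: str, candidate: str, parent: str,
                  alignment: CodonAlignment | None = None) -> PseudogeneCall:
    """Functional iff no ORF disruption is detected."""
    d = detect_disruptions(candidate, parent, alignment)
    status = "nonfunctional" if d else "functional"
    return PseudogeneCall(gene_id, status, tuple(d))


def classify(items: list[tuple[str, str, str]]) -> list[PseudogeneCall]:
    """Classify ``(gene_id, candidate, parent)`` triples."""
    return [classify_gene(gid, cand, par) for gid, cand, par in items]


def degeneration_proportion(
    calls: list[PseudogeneCall], ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of nonfunctional copies with an exact binomial CI."""
    if not calls:
        raise ValueError("no pseudogene calls to summarize")
    k = sum(1 for c in calls if c.status == "nonfunctional")
    n = len(calls)
    ci = binomtest(k, n).proportion_ci(confidence_level=ci_level, method="exact")
    return k / n, (float(ci.low), float(ci.high))
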