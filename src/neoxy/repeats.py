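"""Repeat density, sex-differential enrichment and divergence landscapes.

Densities are percent of repeat-derived bases per window after merging
overlapping hits; enrichment compares a family's abundance between the male
and female genomes at a configurable fold threshold (1.1x by default, the
conventional cut-off for calling a repeat sex-enriched); landscapes histogram
repeat abundance by percent divergence from the family consensus in 1% bins,
so recently amplified families (e.g. satellite DNA) pile up near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, RepeatHit


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def repeat_density_windows(
    hits: list[RepeatHit],
    genome_lengths: dict[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Percent of repeat-derived bases per window (overlaps merged, so each
    base counts once)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        iv = h.interval
        if iv.chrom not in genome_lengths:
            raise ValueError(f"hit on unknown chromosome {iv.chrom}")
        if iv.end > genome_lengths[iv.chrom]:
            raise ValueError(
                f"hit {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
            )
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    frames = []
    for chrom, length in genome_lengths.items():
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        covered = np.zeros(len(starts))
        for s, e in _merge(by_chrom.get(chrom, [])):
            lo = s // window
            hi = (e - 1) // window
            for w in range(lo, hi + 1):
                covered[w] += min(e, (w + 1) * window) - max(s, w * window)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "density_pct": 100.0 * covered / (ends - starts),
        }))
    return pd.concat(frames, ignore_index=True)


def compare_region_density(
    density: pd.DataFrame, region: GenomicInterval
) -> tuple[float, float, float, float]:
    """Mann-Whitney U comparison of window densities inside vs outside a
    region (two-sided, continuity-corrected normal approximation; exact
    enumeration when both sides have <= 8 windows and no ties).

    Returns ``(median_inside, median_outside, U, p)``. A window counts as
    inside when its midpoint falls in the region.
    """
    mid = (density["start"] + density["end"]) // 2
    inside_mask = (
        (density["chrom"] == region.chrom)
        & (mid >= region.start)
        & (mid < region.end)
    )
    inside = density.loc[inside_mask, "density_pct"].to_numpy(float)
    outside = density.loc[~inside_mask, "density_pct"].to_numpy(float)
    if len(inside) < 3 or len(outside) < 3:
        raise ValueError("need at least 3 windows on each side of the region")
    if np.all(inside == inside[0]) and np.all(outside == inside[0]):
        return float(inside[0]), float(inside[0]), len(inside) * len(outside) / 2.0, 1.0
    pooled = np.concatenate([inside, outside])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(inside), len(outside)) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(inside, outside, alternative="two-sided",
                             use_continuity=True, method=method)
    return (float(np.median(inside)), float(np.median(outside)),
            float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class EnrichmentRecord:
    family: str
    mf_ratio: float  # male / female abundance
    fm_ratio: float
    call: str  # male_enriched | female_enriched | none


def abundance_table(
    hits_by_sex: dict[str, list[RepeatHit]], genome_length: int
) -> pd.DataFrame:
    """Per-family abundance as percent of assayed bases in each sex."""
    rows: dict[str, dict[str, float]] = {}
    classes: dict[str, str] = {}
    for sex, hits in hits_by_sex.items():
        for h in hits:
            rows.setdefault(h.family, {"M": 0.0, "F": 0.0})
            rows[h.family][sex] += len(h.interval)
            classes[h.family] = h.repeat_class
    return pd.DataFrame([
        {
            "family": fam,
            "repeat_class": classes[fam],
            "male_pct": 100.0 * v["M"] / genome_length,
            "female_pct": 100.0 * v["F"] / genome_length,
        }
        for fam, v in sorted(rows.items())
    ])


def sex_enrichment(
    table: pd.DataFrame, threshold: float = 1.1
) -> list[EnrichmentRecord]:
    """Call families male- or female-enriched at a fold-ratio threshold.

    The threshold comparison is inclusive (ratio >= threshold). A family
    absent from one sex but present in the other is enriched with an infinite
    ratio; families absent from both are skipped with a warning.
    """
    records = []
    for _, row in table.iterrows():
        m, f = float(row["male_pct"]), float(row["female_pct"])
        if m == 0 and f == 0:
            warnings.warn(f"family {row['family']} absent from both sexes; skipped")
            continue
        mf = m / f if f > 0 else float("inf")
        fm = f / m if m > 0 else float("inf")
        if mf >= threshold:
            call = "male_enriched"
        elif fm >= threshold:
            call = "female_enriched"
        else:
            call = "none"
        records.append(EnrichmentRecord(str(row["family"]), mf, fm, call))
    records.sort(key=lambda r: -max(r.mf_ratio, r.fm_ratio))
    return records


def divergence_landscape(
    hits: list[RepeatHit], genome_length: int, n_bins: int = 100
) -> pd.DataFrame:
    """Histogram of repeat abundance by divergence, in 1% bins [0,1), [1,2)...

    Bin value is the percent of assayed bases contributed by hits whose
    divergence falls in the bin; bin masses sum to the total repeat percent
    (hit lengths summed without merging).
    """
    mass = np.zeros(n_bins)
    for h in hits:
        b = min(int(h.divergence), n_bins - 1)
        mass[b] += len(h.interval)
    return pd.DataFrame({
        "divergence_bin": np.arange(n_bins),
        "percent": 100.0 * mass / genome_length,
    })
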