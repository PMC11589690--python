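"""Windowed male/female coverage and heterozygosity scan.

Per-sample depth is normalized by that sample's genome-wide median window
depth, so diploid regions sit at 1.0 and male-hemizygous regions at ~0.5.
Outlier windows are flagged against the empirical percentile interval of the
genome-wide window distribution, and runs of flagged windows are called as
candidate sex-linked regions:

* ``homogametic`` — male coverage about half of female (hemizygous X/XL) and
  male heterozygosity below female;
* ``heterogametic`` — equal coverage but male heterozygosity elevated by
  fixed X-Y differences (the non-recombining neo-XY stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, VariantRecord

DEFAULT_CI = 0.95


@dataclass(frozen=True)
class SexLinkedRegion:
    """A called sex-linked interval with its supporting window evidence."""

    interval: GenomicInterval
    region_class: str  # autosomal | homogametic | heterogametic
    n_windows: int
    mean_cov_ratio: float
    mean_het_diff: float

    def length_mb(self) -> float:
        return region_length_mb(self.interval)


def region_length_mb(interval: GenomicInterval) -> float:
    """Interval length in megabases."""
    return (interval.end - interval.start) / 1e6


def _window_index(length: int, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    return starts, ends


def window_stats(
    coverage: dict[str, pd.DataFrame],
    variants: list[VariantRecord] | None,
    variant_samples: list[str] | None,
    sexes: dict[str, str],
    window_size: int,
    min_depth: int = 3,
    min_callable: int = 100,
) -> pd.DataFrame:
    """Per-window, per-sample normalized coverage and heterozygosity.

    ``coverage`` maps sample -> bedgraph-style frame (chrom, start, end,
    depth). Heterozygosity is heterozygous calls over callable sites (bases
    where every sample reaches ``min_depth``), and is NaN where fewer than
    ``min_callable`` sites are callable.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    missing = [s for s in sexes if s not in coverage]
    if missing:
        raise ValueError(f"samples in sex table lack coverage tracks: {missing}")
    samples = [s for s in sexes]

    chrom_lengths: dict[str, int] = {}
    for track in coverage.values():
        ends = track.groupby("chrom")["end"].max()
        for chrom, end in ends.items():
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), int(end))

    frames = []
    for chrom in chrom_lengths:
        starts, ends = _window_index(chrom_lengths[chrom], window_size)
        n_win = len(starts)
        widths = (ends - starts).astype(float)

        cov = np.zeros((len(samples), n_win))
        callable_bases = np.full((len(samples), n_win), np.inf)
        for si, sample in enumerate(samples):
            t = coverage[sample]
            t = t[t["chrom"] == chrom]
            b_start = t["start"].to_numpy(np.int64)
            b_end = t["end"].to_numpy(np.int64)
            depth = t["depth"].to_numpy(float)
            cov_sum = np.zeros(n_win)
            call_sum = np.zeros(n_win)
            w_lo = b_start // window_size
            w_hi = (b_end - 1) // window_size
            simple = w_lo == w_hi
            blen = (b_end - b_start).astype(float)
            np.add.at(cov_sum, w_lo[simple], depth[simple] * blen[simple])
            np.add.at(call_sum, w_lo[simple],
                      np.where(depth[simple] >= min_depth, blen[simple], 0.0))
            for i in np.nonzero(~simple)[0]:  # bins crossing a window boundary
                lo, hi = b_start[i], b_end[i]
                while lo < hi:
                    w = lo // window_size
                    nxt = min(hi, (w + 1) * window_size)
                    cov_sum[w] += depth[i] * (nxt - lo)
                    if depth[i] >= min_depth:
                        call_sum[w] += nxt - lo
                    lo = nxt
            cov[si] = cov_sum / widths
            callable_bases[si] = call_sum
        callable_sites = callable_bases.min(axis=0)

        frame = pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "callable": callable_sites.astype(np.int64),
        })
        for si, sample in enumerate(samples):
            frame[f"cov_{sample}"] = cov[si]
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)

    # normalize per sample by genome-wide median window coverage
    for sample in samples:
        col = f"cov_{sample}"
        med = table[col].median()
        if med <= 0:
            raise ValueError(f"sample {sample} has zero median coverage")
        table[col] = table[col] / med

    # heterozygosity per sample per window
    for sample in samples:
        table[f"het_{sample}"] = 0.0
    if variants:
        if variant_samples is None:
            raise ValueError("variant_samples required when variants are given")
        vs_index = {s: i for i, s in enumerate(variant_samples)}
        for s in samples:
            if s not in vs_index:
                raise ValueError(f"sample {s} absent from variant calls")
        chroms = np.array([r.chrom for r in variants])
        pos = np.array([r.start for r in variants], dtype=np.int64)
        sel = [vs_index[s] for s in samples]
        if sel == list(range(len(variant_samples))):
            het = np.array([[g.is_het for g in r.genotypes] for r in variants],
                           dtype=np.int32)
        else:
            het = np.array(
                [[r.genotypes[i].is_het for i in sel] for r in variants],
                dtype=np.int32,
            )
        key = table.set_index(["chrom"]).groupby(level=0).indices
        for chrom in chrom_lengths:
            sel = chroms == chrom
            if not sel.any():
                continue
            widx = pos[sel] // window_size
            rows = key[chrom]
            counts = np.zeros((len(rows), len(samples)))
            np.add.at(counts, widx, het[sel])
            for si, sample in enumerate(samples):
                table.loc[rows, f"het_{sample}"] = counts[:, si]
        for sample in samples:
            table[f"het_{sample}"] = (
                table[f"het_{sample}"] / table["callable"].clip(lower=1)
            )
    callable_ok = table["callable"] >= min_callable
    for sample in samples:
        table.loc[~callable_ok, f"het_{sample}"] = np.nan
    return table


def sex_difference_table(table: pd.DataFrame, sexes: dict[str, str]) -> pd.DataFrame:
    """Collapse per-sample window statistics into male/female contrasts."""
    males = [s for s, sex in sexes.items() if sex == "M"]
    females = [s for s, sex in sexes.items() if sex == "F"]
    if not males or not females:
        raise ValueError("need at least one sample of each sex")
    out = table[["chrom", "start", "end", "callable"]].copy()
    out["cov_m"] = table[[f"cov_{s}" for s in males]].mean(axis=1)
    out["cov_f"] = table[[f"cov_{s}" for s in females]].mean(axis=1)
    out["cov_diff"] = out["cov_f"] - out["cov_m"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cov_ratio"] = out["cov_m"] / out["cov_f"]
    out["het_m"] = table[[f"het_{s}" for s in males]].mean(axis=1)
    out["het_f"] = table[[f"het_{s}" for s in females]].mean(axis=1)
    out["het_diff"] = out["het_m"] - out["het_f"]
    return out


def flag_outlier_windows(diff_table: pd.DataFrame,
                         ci_level: float = DEFAULT_CI) -> pd.DataFrame:
    """Flag windows outside the empirical percentile confidence band.

    The band is the [(1-ci)/2, 1-(1-ci)/2] percentile interval of each
    statistic's genome-wide window distribution; under homogeneity the
    expected flagged fraction per statistic is 1 - ci.
    """
    if len(diff_table) < 20:
        raise ValueError("need at least 20 windows to estimate the confidence band")
    out = diff_table.copy()
    alpha = 1.0 - ci_level
    for stat, (low_flag, high_flag) in (
        ("cov_ratio", ("cov_low", "cov_high")),
        ("het_diff", ("het_low", "het_high")),
    ):
        values = out[stat].to_numpy(float)
        finite = values[np.isfinite(values)]
        if len(finite) == 0 or np.nanstd(finite) == 0:
            warnings.warn(f"statistic {stat} is constant; no windows flagged")
            out[low_flag] = False
            out[high_flag] = False
            continue
        # symmetric order statistics rather than interpolated quantiles: the
        # band then maps exactly under monotone transforms of the statistic,
        # so swapping sex labels swaps low/high flags exactly
        srt = np.sort(finite)
        k = int(np.floor(alpha / 2 * (len(srt) - 1)))
        lo, hi = srt[k], srt[len(srt) - 1 - k]
        with np.errstate(invalid="ignore"):
            out[low_flag] = values < lo
            out[high_flag] = values > hi
    return out


def _flag_runs(flagged: np.ndarray, min_run: int, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of flagged windows allowing short interior gaps.

    Returns (first, last) window indices (inclusive) for runs containing at
    least ``min_run`` flagged windows; runs start and end on flagged windows.
    """
    idx = np.nonzero(flagged)[0]
    runs = []
    if len(idx) == 0:
        return runs
    start = prev = idx[0]
    count = 1
    for i in idx[1:]:
        if i - prev <= max_gap + 1:
            prev = i
            count += 1
        else:
            if count >= min_run:
                runs.append((int(start), int(prev)))
            start = prev = i
            count = 1
    if count >= min_run:
        runs.append((int(start), int(prev)))
    return runs


def call_regions(
    flagged: pd.DataFrame,
    min_run: int = 3,
    max_gap: int = 1,
    hom_max_ratio: float = 0.75,
    het_ratio_band: tuple[float, float] = (0.85, 1.15),
    het_excess: float = 1.5,
) -> list[SexLinkedRegion]:
    """Call sex-linked regions from flagged windows.

    Heterogametic candidates are runs of ``het_high`` windows; homogametic
    candidates are runs of ``cov_low`` windows. A candidate is kept as

    * homogametic when mean M/F coverage ratio <= ``hom_max_ratio`` and male
      heterozygosity is below female;
    * heterogametic when the ratio lies within ``het_ratio_band`` and male
      heterozygosity is at least ``het_excess`` times female.

    A candidate satisfying the coverage rule for homogametic but the
    heterozygosity rule for heterogametic is emitted as homogametic with a
    conflict warning; candidates matching neither rule are dropped.
    """
    if not {"het_high", "cov_low"} <= set(flagged.columns):
        raise ValueError("flags not computed; run flag_outlier_windows first")
    regions: list[SexLinkedRegion] = []
    seen: set[tuple[str, int, int]] = set()
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        for flag_col in ("het_high", "cov_low"):
            for lo, hi in _flag_runs(sub[flag_col].to_numpy(bool), min_run, max_gap):
                win = sub.iloc[lo:hi + 1]
                key = (chrom, int(win["start"].iloc[0]), int(win["end"].iloc[-1]))
                if key in seen:
                    continue
                ratio = float(np.nanmean(win["cov_ratio"]))
                het_m = float(np.nanmean(win["het_m"]))
                het_f = float(np.nanmean(win["het_f"]))
                het_excess_met = het_m >= het_excess * het_f and het_m > 0
                region_class = None
                if ratio <= hom_max_ratio:
                    if het_excess_met:
                        warnings.warn(
                            f"conflicting evidence at {chrom}:{key[1]}-{key[2]}: "
                            "hemizygous coverage but excess male heterozygosity; "
                            "calling homogametic"
                        )
                        region_class = "homogametic"
                    elif het_m < het_f:
                        region_class = "homogametic"
                elif het_ratio_band[0] <= ratio <= het_ratio_band[1] and het_excess_met:
                    region_class = "heterogametic"
                if region_class is None:
                    warnings.warn(
                        f"candidate run at {chrom}:{key[1]}-{key[2]} matches no "
                        "class (ratio {:.2f}); dropped".format(ratio)
                    )
                    continue
                seen.add(key)
                regions.append(SexLinkedRegion(
                    interval=GenomicInterval(chrom, key[1], key[2], name=region_class),
                    region_class=region_class,
                    n_windows=len(win),
                    mean_cov_ratio=ratio,
                    mean_het_diff=float(np.nanmean(win["het_diff"])),
                ))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def classify_genome(
    regions: list[SexLinkedRegion], chrom_lengths: dict[str, int]
) -> list[GenomicInterval]:
    """Complete BED classification: called regions plus autosomal remainder."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[SexLinkedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for r in sorted(by_chrom.get(chrom, []), key=lambda r: r.interval.start):
            if r.interval.start > cursor:
                out.append(GenomicInterval(chrom, cursor, r.interval.start,
                                           name="autosomal"))
            out.append(GenomicInterval(chrom, r.interval.start, r.interval.end,
                                       name=r.region_class))
            cursor = r.interval.end
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length, name="autosomal"))
    return out
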