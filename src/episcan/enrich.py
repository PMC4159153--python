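"""Regulatory enrichment statistics.

Two analyses: (1) enhancer-overlap enrichment of a tagged SNP set against
the genotyped-SNP background — the expected overlap count is the tagged-set
size times the background overlap frequency, the fold is observed/expected
and the P-value is the upper-tail exact binomial; (2) chromatin-interaction
(ChIA-PET) density around trait regions — marginal SNPs are greedily
clustered into 25-kb regions, interactions whose either anchor overlaps a
+-100-kb window around each region midpoint are counted, and a focal region
is ranked by the fraction of regions with strictly more interactions.

SNP positions are 1-based; BED/BEDPE intervals are 0-based half-open.  A
SNP position is flagged inside an interval iff start <= pos < end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import round_half_up

__all__ = ["EnrichmentResult", "overlap_flags", "enrichment_test", "bin_snps",
           "count_chiapet", "empirical_rank"]


@dataclass
class EnrichmentResult:
    """Observed vs expected overlap of a tagged SNP set with one annotation."""

    cell_type: str
    n_tagged: int
    observed: int
    expected: float
    fold: float
    p: float

    def __post_init__(self):
        if self.observed > self.n_tagged:
            raise ValueError("observed cannot exceed n_tagged")


def overlap_flags(positions, track: pd.DataFrame, chroms=None) -> np.ndarray:
    """Flag SNP positions falling inside half-open BED intervals.

    ``track`` needs columns chrom/start/end; intervals are sorted internally
    (with a warning) if needed.  ``chroms`` gives each SNP's chromosome; if
    omitted all SNPs and intervals are assumed co-chromosomal.
    """
    positions = np.asarray(positions, dtype=np.int64)
    flags = np.zeros(positions.size, dtype=bool)
    if len(track) == 0:
        return flags
    if chroms is None:
        chroms = np.repeat(track["chrom"].iloc[0], positions.size)
    chroms = np.asarray(chroms)
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if np.any(np.diff(starts) < 0):
            warnings.warn("unsorted BED track; sorting internally", stacklevel=2)
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
        sel = chroms == chrom
        pos = positions[sel]
        # rightmost interval with start <= pos; intervals may overlap, so
        # fall back to a bounded backward check
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = np.zeros(pos.size, dtype=bool)
        max_len = int((ends - starts).max()) if len(sub) else 0
        for k, (p, i) in enumerate(zip(pos, idx)):
            j = i
            while j >= 0 and starts[j] > p - max_len - 1:
                if starts[j] <= p < ends[j]:
                    hit[k] = True
                    break
                j -= 1
        flags[sel] = hit
    return flags


def enrichment_test(n_tagged: int, observed: int, background_overlap_freq: float,
                    cell_type: str = "") -> EnrichmentResult:
    """Upper-tail binomial enrichment against the genotyped-SNP background.

    expected = n_tagged * freq; fold = observed/expected rounded half-up to
    one decimal; p = P(X >= observed), X ~ Binomial(n_tagged, freq).
    """
    if not (0.0 < background_overlap_freq < 1.0):
        raise ValueError("background overlap frequency must be in (0, 1)")
    if observed > n_tagged:
        raise ValueError("observed cannot exceed n_tagged")
    expected = n_tagged * background_overlap_freq
    fold = round_half_up(observed / expected, 1)
    p = float(stats.binom.sf(observed - 1, n_tagged, background_overlap_freq))
    return EnrichmentResult(cell_type, n_tagged, observed, expected, fold, p)


def bin_snps(positions, chroms=None, bin_span: int = 25_000) -> pd.DataFrame:
    """Greedy left-to-right clustering of sorted SNP positions into regions.

    A region opens at the first unassigned SNP and absorbs every subsequent
    SNP within ``bin_span`` of that first SNP; its span is
    [first_snp, first_snp + bin_span).  Returns a DataFrame with chrom,
    start, end, midpoint, n_snps.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if chroms is None:
        chroms = np.repeat("1", positions.size)
    chroms = np.asarray(chroms)
    rows = []
    for chrom in pd.unique(chroms):
        pos = np.sort(positions[chroms == chrom])
        i = 0
        while i < pos.size:
            first = pos[i]
            j = i
            while j < pos.size and pos[j] - first < bin_span:
                j += 1
            rows.append({"chrom": chrom, "start": int(first),
                         "end": int(first + bin_span),
                         "midpoint": float(first + bin_span / 2.0),
                         "n_snps": int(j - i)})
            i = j
    return pd.DataFrame(rows)


def count_chiapet(bins: pd.DataFrame, interactions: pd.DataFrame,
                  flank: int = 100_000) -> pd.DataFrame:
    """Count interactions whose either anchor overlaps each bin's +-flank window.

    The window is [midpoint - flank, midpoint + flank] (closed); an anchor
    [start, end) overlaps it iff start <= midpoint + flank and
    end > midpoint - flank, on the same chromosome.  Each interaction counts
    at most once per bin.  Malformed rows (end <= start or non-numeric) are
    skipped with a warning.
    """
    bins = bins.copy()
    counts = np.zeros(len(bins), dtype=np.int64)
    clean = []
    for _, row in interactions.iterrows():
        try:
            r = (str(row["chrom1"]), int(row["start1"]), int(row["end1"]),
                 str(row["chrom2"]), int(row["start2"]), int(row["end2"]))
        except (ValueError, TypeError, KeyError):
            warnings.warn("malformed BEDPE row skipped", stacklevel=2)
            continue
        if r[2] <= r[1] or r[5] <= r[4]:
            warnings.warn("malformed BEDPE row skipped", stacklevel=2)
            continue
        clean.append(r)
    for b, (_, brow) in enumerate(bins.iterrows()):
        lo = brow["midpoint"] - flank
        hi = brow["midpoint"] + flank
        chrom = str(brow["chrom"])
        for c1, s1, e1, c2, s2, e2 in clean:
            hit1 = c1 == chrom and s1 <= hi and e1 > lo
            hit2 = c2 == chrom and s2 <= hi and e2 > lo
            if hit1 or hit2:
                counts[b] += 1
    bins["chiapet_count"] = counts
    return bins


def empirical_rank(counts, focal: int):
    """Fraction of regions with strictly more interactions than the focal one.

    ``focal`` may be an index into ``counts``; returns (fraction, numerator,
    denominator).  Strict inequality: if every region ties the focal count
    the fraction is 0.
    """
    counts = np.asarray(counts)
    if counts.size < 2:
        raise ValueError("need at least 2 regions")
    focal_count = counts[focal]
    num = int((counts > focal_count).sum())
    return num / counts.size, num, int(counts.size)
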