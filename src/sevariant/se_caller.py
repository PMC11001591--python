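"""Super-enhancer calling from H3K27ac peaks (ROSE-style).

The procedure: drop peaks within a fixed window of annotated transcription
start sites, stitch the survivors whose genomic gap is at most the stitch
distance (12.5 kb by default) into candidate enhancer regions, rank the
regions by total H3K27ac signal, and classify as super-enhancers (SEs) all
regions whose signal lies strictly above the rank-curve tangency point of a
line with slope one (after rescaling both axes so the full curve's secant
has slope one).  Condition-specific SE sets are obtained by subtracting any
SE that overlaps a background condition's SE and removing excluded
chromosomes (chrX by default).

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_WINDOW = 2_500
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX"})


@dataclass(frozen=True)
class Peak:
    """A signal-carrying genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    signal: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name!r}: start {self.start} >= end {self.end}")
        if self.signal < 0:
            raise ValueError(f"peak {self.name!r}: negative signal {self.signal}")


@dataclass
class StitchedEnhancer:
    """A maximal run of peaks whose pairwise gaps are within the stitch distance."""

    chrom: str
    start: int
    end: int
    constituents: list[Peak]
    total_signal: float
    rank: int = 0  # 1-based ascending by total_signal, assigned by call_threshold


@dataclass
class SECallResult:
    """Ranked stitched enhancers partitioned into SEs and typical enhancers."""

    ranked: list[StitchedEnhancer]  # ascending by total_signal
    cutoff_signal: float
    cutoff_rank: int  # 1-based rank of the tangency point
    se_set: list[StitchedEnhancer]
    te_set: list[StitchedEnhancer]

    def rank_table(self) -> pd.DataFrame:
        """Rank-vs-signal table (the hockey-stick curve), cutoff annotated."""
        rows = [
            {
                "rank": e.rank,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "total_signal": e.total_signal,
                "n_constituents": len(e.constituents),
                "is_se": e.total_signal > self.cutoff_signal,
            }
            for e in self.ranked
        ]
        return pd.DataFrame(rows)


def _tss_trees(tss: pd.DataFrame, window: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in tss.groupby("chrom"):
        tree = IntervalTree()
        for pos in sub["pos"].to_numpy():
            lo = int(pos) - window
            hi = int(pos) + window
            if hi > lo:
                tree[lo:hi] = True
        trees[str(chrom)] = tree
    return trees


def exclude_tss_proximal(
    peaks: list[Peak], tss: pd.DataFrame, window: int = DEFAULT_TSS_WINDOW
) -> list[Peak]:
    """Remove peaks overlapping any TSS +/- ``window`` interval.

    ``tss`` needs columns ``chrom`` and ``pos`` (a TSS is a point; strand is
    irrelevant to the symmetric window).  A peak on a chromosome absent from
    the annotation is retained — there is no TSS near it.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    if len(tss) == 0:
        return list(peaks)
    trees = _tss_trees(tss, window)
    kept = []
    n_unknown = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            n_unknown += 1
            kept.append(p)
        elif not tree.overlaps(p.start, p.end):
            kept.append(p)
    if n_unknown:
        logger.info("exclude_tss_proximal: %d peaks on chromosomes without TSS retained", n_unknown)
    return kept


def stitch(peaks: list[Peak], distance: int = DEFAULT_STITCH_DISTANCE) -> list[StitchedEnhancer]:
    """Merge peaks whose gap (next.start - prev.end) is <= ``distance``.

    Overlapping peaks have gap <= 0 and always merge.  The merge is the
    transitive closure per chromosome.
    """
    if distance < 0:
        raise ValueError(f"stitch distance must be >= 0, got {distance}")
    out: list[StitchedEnhancer] = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        cur = out[-1] if out else None
        if cur is not None and cur.chrom == p.chrom and p.start - cur.end <= distance:
            cur.constituents.append(p)
            cur.end = max(cur.end, p.end)
            cur.total_signal += p.signal
        else:
            out.append(StitchedEnhancer(p.chrom, p.start, p.end, [p], p.signal))
    return out


def call_threshold(stitched: list[StitchedEnhancer]) -> SECallResult:
    """Classify stitched enhancers by the slope-one tangency threshold.

    Sort ascending by total signal; rescale so the secant over the full curve
    has slope one, i.e. work with slope s = (max - min) / (n - 1) in signal
    units per rank.  The cutoff index is the unique i* such that the line of
    slope s through point i* lies on or below every point of the curve
    (equivalently i* = argmin_i y_i - s*i); ties go to the smallest index,
    which yields the larger SE set.  SEs are the regions with total signal
    strictly above the cutoff signal.
    """
    n = len(stitched)
    if n < 3:
        raise ValueError(f"need >= 3 stitched enhancers to place a threshold, got {n}")
    ranked = sorted(stitched, key=lambda e: e.total_signal)
    y = np.array([e.total_signal for e in ranked], dtype=float)
    if y[0] == y[-1]:
        raise ValueError("degenerate curve: all stitched enhancers have identical signal")
    for i, e in enumerate(ranked):
        e.rank = i + 1
    s = (y[-1] - y[0]) / (n - 1)
    z = y - s * np.arange(n)
    # ties (within floating tolerance) break toward the smallest rank,
    # which yields the larger SE set
    tol = 1e-9 * max(1.0, float(np.abs(y).max()))
    istar = int(np.flatnonzero(z <= z.min() + tol)[0])
    cutoff = float(y[istar])
    se = [e for e in ranked if e.total_signal > cutoff]
    te = [e for e in ranked if e.total_signal <= cutoff]
    return SECallResult(ranked=ranked, cutoff_signal=cutoff, cutoff_rank=istar + 1, se_set=se, te_set=te)


def call_ses(
    peaks: list[Peak],
    tss: pd.DataFrame,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> SECallResult:
    """Full SE call: TSS exclusion -> stitching -> tangency threshold."""
    kept = exclude_tss_proximal(peaks, tss, tss_window)
    if not kept:
        raise ValueError("no peaks remain after the TSS-proximity exclusion filter")
    return call_threshold(stitch(kept, stitch_distance))


def specific_ses(
    target: SECallResult,
    backgrounds: list[SECallResult],
    exclude_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDE_CHROMS,
) -> tuple[list[StitchedEnhancer], dict[str, int]]:
    """Target SEs not overlapping any background SE, excluded chromosomes removed.

    Overlap is any-overlap (>= 1 bp).  Returns the retained SEs and the counts
    of each removal class.
    """
    bg_trees: dict[str, IntervalTree] = {}
    for bg in backgrounds:
        for e in bg.se_set:
            bg_trees.setdefault(e.chrom, IntervalTree())[e.start:e.end] = True

    kept: list[StitchedEnhancer] = []
    counts = {"input": len(target.se_set), "removed_background_overlap": 0, "removed_chrom": 0}
    for e in target.se_set:
        if e.chrom in bg_trees and bg_trees[e.chrom].overlaps(e.start, e.end):
            counts["removed_background_overlap"] += 1
        elif e.chrom in exclude_chroms:
            counts["removed_chrom"] += 1
        else:
            kept.append(e)
    counts["kept"] = len(kept)
    logger.info(
        "specific_ses: %(input)d target SEs, %(removed_background_overlap)d removed by "
        "background overlap, %(removed_chrom)d removed by chromosome filter, %(kept)d kept",
        counts,
    )
    return kept, counts
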