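"""Enhancer definition, stitching, and super-enhancer calling.

The procedure follows the ROSE approach: H3K27ac peaks (optionally first
restricted to "potential enhancers" that also carry H3K4me1) are cleansed of
promoter peaks lying wholly within a TSS exclusion window, transitively
stitched when their genomic gap is at most the stitch distance (12.5 kb by
default), ranked by combined H3K27ac signal, and split into super-enhancers
(SE) and typical enhancers (TE) at the inflection point of the scaled
signal-vs-rank curve -- the rank at which a line of slope 1 is tangent to
the curve rescaled to the unit square.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_model import (
    GeneModel,
    GenomicInterval,
    SignalPeak,
    intersect_any,
)

__all__ = [
    "StitchingParams",
    "StitchedEnhancer",
    "define_potential_enhancers",
    "stitch",
    "call_super_enhancers",
    "se_counts_by_replicate",
    "annotate_genomic_distribution",
    "GENOMIC_CATEGORIES",
]


@dataclass(frozen=True)
class StitchingParams:
    """Stitch distance and promoter-exclusion half-width, both in bp."""

    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500

    def __post_init__(self) -> None:
        if self.stitch_distance < 0 or self.tss_exclusion < 0:
            raise ValueError("stitching parameters must be >= 0")


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its constituent peaks.

    ``signal_by_replicate`` holds the per-replicate sums of constituent-peak
    signal; ``total_signal`` (used for ranking) is the replicate mean of those
    sums.
    """

    interval: GenomicInterval
    constituent_peaks: list[SignalPeak]
    signal_by_replicate: np.ndarray
    enhancer_id: str = ""
    rank: int | None = None
    is_super: bool | None = None

    @property
    def total_signal(self) -> float:
        return float(np.mean(self.signal_by_replicate))

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def enhancer_class(self) -> str:
        return "SE" if self.is_super else "TE"


def define_potential_enhancers(
    h3k27ac: Sequence[SignalPeak], h3k4me1: Iterable[SignalPeak]
) -> list[SignalPeak]:
    """H3K27ac peaks that also carry H3K4me1 (>= 1 bp overlap)."""
    if len(h3k27ac) == 0:
        warnings.warn("empty H3K27ac peak set: no potential enhancers")
        return []
    return intersect_any(h3k27ac, h3k4me1)


def _tss_positions(genes: Iterable) -> dict[str, list[int]]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        if isinstance(g, GeneModel):
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        else:
            chrom, pos = g
            by_chrom.setdefault(chrom, []).append(int(pos))
    for positions in by_chrom.values():
        positions.sort()
    return by_chrom


def _contained_in_tss_window(peak: SignalPeak, tss_sorted: list[int], excl: int) -> bool:
    # peak wholly inside [tss - excl, tss + excl]  <=>  a TSS exists in
    # [end - excl, start + excl]
    iv = peak.interval
    lo, hi = iv.end - excl, iv.start + excl
    if lo > hi:
        return False
    idx = bisect_left(tss_sorted, lo)
    return idx < len(tss_sorted) and tss_sorted[idx] <= hi


def stitch(
    peaks: Sequence[SignalPeak],
    genes: Iterable,
    params: StitchingParams = StitchingParams(),
) -> list[StitchedEnhancer]:
    """Stitch peaks into enhancer regions.

    Peaks wholly contained in any TSS +/- ``tss_exclusion`` window are
    removed first; surviving peaks on the same chromosome are merged
    transitively whenever the gap between them is <= ``stitch_distance``.
    ``genes`` may be :class:`GeneModel` objects or ``(chrom, tss)`` pairs.
    """
    n_reps = {pk.n_replicates for pk in peaks}
    if len(n_reps) > 1:
        raise ValueError(f"inconsistent replicate counts across peaks: {sorted(n_reps)}")
    tss_by_chrom = _tss_positions(genes)
    kept = [
        pk
        for pk in peaks
        if not _contained_in_tss_window(
            pk, tss_by_chrom.get(pk.interval.chrom, []), params.tss_exclusion
        )
    ]
    kept.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start, pk.interval.end))

    enhancers: list[StitchedEnhancer] = []
    cluster: list[SignalPeak] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(pk.interval.start for pk in cluster)
        end = max(pk.interval.end for pk in cluster)
        signal = np.sum([pk.signal_by_replicate for pk in cluster], axis=0, dtype=float)
        enhancers.append(
            StitchedEnhancer(
                interval=GenomicInterval(cluster[0].interval.chrom, start, end),
                constituent_peaks=list(cluster),
                signal_by_replicate=signal,
            )
        )
        cluster.clear()

    cur_chrom, cur_end = None, -1
    for pk in kept:
        iv = pk.interval
        if cluster and (iv.chrom != cur_chrom or iv.start - cur_end > params.stitch_distance):
            flush()
        cluster.append(pk)
        if iv.chrom != cur_chrom:
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            cur_end = max(cur_end, iv.end)
        cur_chrom = iv.chrom
    flush()

    for i, enh in enumerate(enhancers):
        enh.enhancer_id = f"enh_{i + 1}"
    return enhancers


def _inflection_threshold(signals: np.ndarray) -> tuple[float | None, int | None]:
    """Signal threshold at the inflection point of the scaled rank curve.

    Signals must be sorted ascending.  Both axes are rescaled to [0, 1]; the
    inflection point is the rank where a line of slope 1 is tangent to the
    scaled curve from below, i.e. the global maximizer of ``x - y`` (where
    the discrete slope crosses 1 in cumulative terms).  Ties break toward
    the lower rank.  The global tangency form is used rather than the first
    local slope crossing because the empirical ranked curve is noisy: a
    single local gap anywhere in the bulk would otherwise set the threshold.
    Returns ``(None, None)`` when the curve never dips below the diagonal
    (linear or constant curves -- no inflection).
    """
    n = len(signals)
    if n < 2 or signals[-1] == signals[0]:
        return None, None
    x = np.arange(n) / (n - 1)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    gap = x - y
    idx = int(np.argmax(gap))  # first occurrence on ties
    if gap[idx] <= 0:
        return None, None
    return float(signals[idx]), idx + 1  # 1-based rank


def call_super_enhancers(
    stitched: Sequence[StitchedEnhancer],
    signals: np.ndarray | None = None,
) -> list[StitchedEnhancer]:
    """Rank stitched enhancers and label those above the inflection point.

    Enhancers are sorted by ascending signal (ties broken by coordinates so
    the call is invariant to input order); every enhancer with signal
    strictly above the threshold is a super-enhancer.  Returns the enhancers
    in rank order with ``rank`` and ``is_super`` set.
    """
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched enhancers to locate an inflection")
    if signals is None:
        signals = np.array([e.total_signal for e in stitched], dtype=float)
    else:
        signals = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite enhancer signal")

    order = sorted(
        range(len(stitched)),
        key=lambda i: (
            signals[i],
            stitched[i].interval.chrom,
            stitched[i].interval.start,
            stitched[i].interval.end,
        ),
    )
    sorted_signals = signals[order]
    threshold, _ = _inflection_threshold(sorted_signals)
    if threshold is None:
        warnings.warn(
            "ranked signal curve has no inflection (slope never exceeds 1); "
            "calling zero super-enhancers"
        )
    ranked = []
    for rank0, i in enumerate(order):
        enh = stitched[i]
        enh.rank = rank0 + 1
        enh.is_super = threshold is not None and signals[i] > threshold
        ranked.append(enh)
    return ranked


def se_counts_by_replicate(
    stitched: Sequence[StitchedEnhancer],
) -> dict:
    """Per-replicate SE/TE calls on the same stitched regions.

    The caller is run once per replicate signal vector; reported counts are
    the arithmetic means over replicates (how replicate experiments are
    summarized into a single "average total").  Also returns the consensus
    labels (super in every replicate).
    """
    if not stitched:
        raise ValueError("no stitched enhancers")
    n_reps = len(stitched[0].signal_by_replicate)
    per_rep_super: list[np.ndarray] = []
    for r in range(n_reps):
        sig = np.array([e.signal_by_replicate[r] for e in stitched], dtype=float)
        labels = np.zeros(len(stitched), dtype=bool)
        order = sorted(
            range(len(stitched)),
            key=lambda i: (
                sig[i],
                stitched[i].interval.chrom,
                stitched[i].interval.start,
            ),
        )
        threshold, _ = _inflection_threshold(sig[order])
        if threshold is not None:
            labels = sig > threshold
        per_rep_super.append(labels)
    se_counts = [int(lab.sum()) for lab in per_rep_super]
    te_counts = [len(stitched) - c for c in se_counts]
    consensus = np.logical_and.reduce(per_rep_super)
    return {
        "n_replicates": n_reps,
        "se_count_by_replicate": se_counts,
        "te_count_by_replicate": te_counts,
        "mean_se_count": float(np.mean(se_counts)),
        "mean_te_count": float(np.mean(te_counts)),
        "consensus_super": consensus,
    }


GENOMIC_CATEGORIES = ("Promoter", "Exon", "Intron", "Distal Intergenic")


def annotate_genomic_distribution(
    enhancers: Sequence[StitchedEnhancer],
    genes: Sequence[GeneModel],
    exons: dict[str, list[GenomicInterval]] | None = None,
    promoter_window: int = 2_500,
) -> tuple[list[str], dict[str, float]]:
    """Assign each enhancer one genomic category by its midpoint.

    Priority: Promoter (midpoint within TSS +/- ``promoter_window``) > Exon >
    Intron > Distal Intergenic.  Without exon structure the whole gene body
    counts as intronic (gene-body fallback).  Returns per-enhancer categories
    and the category proportions (summing to 1 over non-empty input).
    """
    tss_by_chrom = _tss_positions(genes)
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        bodies.setdefault(g.chrom, []).append((g.interval.start, g.interval.end))
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if exons:
        for ivs in exons.values():
            for iv in ivs:
                exon_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def in_any(spans: list[tuple[int, int]], pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    categories: list[str] = []
    for enh in enhancers:
        mid = enh.interval.midpoint
        chrom = enh.interval.chrom
        tss_sorted = tss_by_chrom.get(chrom, [])
        idx = bisect_left(tss_sorted, mid - promoter_window)
        near_tss = idx < len(tss_sorted) and tss_sorted[idx] <= mid + promoter_window
        if near_tss:
            categories.append("Promoter")
        elif in_any(exon_by_chrom.get(chrom, []), mid):
            categories.append("Exon")
        elif in_any(bodies.get(chrom, []), mid):
            categories.append("Intron")
        else:
            categories.append("Distal Intergenic")

    proportions = {
        cat: (categories.count(cat) / len(categories) if categories else 0.0)
        for cat in GENOMIC_CATEGORIES
    }
    return categories, proportions
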