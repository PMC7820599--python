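"""Per-gene read and TF-bound-site aggregation, reproducibility correlation,
TSS meta-profiles, and knockout contrasts.

Per-gene aggregation order matters and is fixed: per enhancer the
replicate signals are averaged, the averages are summed over the gene's
assigned enhancers, and the sum is divided by two to adjust paired-end
counting to one read per fragment.  Per-kilobase densities divide the
per-gene value by the mean assigned-enhancer length in kb.

Per-gene rows are computed per enhancer class: a gene with both SE and TE
assignments contributes one SE row (aggregated over its SEs) and one TE row,
so that SE-vs-TE comparisons of per-gene occupancy are well defined even for
mixed genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import CoverageTrack, _as_interval
from .enhancer_landscape import StitchedEnhancer

__all__ = [
    "reads_per_gene",
    "normalize_per_enhancer",
    "sites_per_gene",
    "signal_at_enhancers",
    "gene_profiles",
    "binned_pearson",
    "tss_meta_profile",
    "knockout_contrast",
    "REDUCTION_BANDS",
]


def _enhancer_mean_signal(enh) -> float:
    sig = np.asarray(enh.signal_by_replicate, dtype=float)
    if sig.ndim != 1 or len(sig) < 1:
        raise ValueError(f"enhancer {getattr(enh, 'enhancer_id', enh)} missing replicate signal")
    return float(sig.mean())


def reads_per_gene(
    assigned_enhancers: Sequence,
    paired_end: bool = True,
) -> float:
    """Replicate-averaged, paired-end-halved enhancer reads for one gene.

    Per enhancer the replicate signals are averaged; the averages are summed
    over all assigned enhancers; the sum is halved when ``paired_end`` (two
    mates per fragment).
    """
    n_reps = {len(np.atleast_1d(e.signal_by_replicate)) for e in assigned_enhancers}
    if len(n_reps) > 1:
        bad = next(
            getattr(e, "enhancer_id", str(e))
            for e in assigned_enhancers
            if len(np.atleast_1d(e.signal_by_replicate)) == min(n_reps)
        )
        raise ValueError(f"inconsistent replicate counts (enhancer {bad})")
    total = sum(_enhancer_mean_signal(e) for e in assigned_enhancers)
    return total / 2.0 if paired_end else total


def normalize_per_enhancer(per_gene_value: float, enhancer_lengths: Sequence[int]) -> float | None:
    """Per-kb density: value divided by the mean enhancer length in kb.

    Returns ``None`` (missing, not zero) for a gene without enhancers.
    """
    if len(enhancer_lengths) == 0:
        return None
    mean_kb = float(np.mean(enhancer_lengths)) / 1000.0
    return per_gene_value / mean_kb


def sites_per_gene(
    assigned_enhancers: Sequence,
    tf_peaks: Iterable,
) -> tuple[int, int]:
    """TF-bound sites at a gene's enhancers.

    A bound site is one TF peak overlapping an enhancer by >= 1 bp.  Returns
    ``(unique_sites, per_enhancer_sum)``: the per-gene total counts each TF
    peak once even when it straddles two enhancers; the per-enhancer sum
    counts it once per overlapped enhancer and is the numerator for per-kb
    densities.
    """
    tf_list = list(tf_peaks)
    seen: set[int] = set()
    per_enh_sum = 0
    for enh in assigned_enhancers:
        iv = _as_interval(enh)
        for j, pk in enumerate(tf_list):
            if iv.overlaps(_as_interval(pk)):
                per_enh_sum += 1
                seen.add(j)
    return len(seen), per_enh_sum


def signal_at_enhancers(
    enhancers: Sequence,
    peaks: Sequence,
) -> list[np.ndarray]:
    """Per-enhancer summed peak signal by replicate (>= 1 bp overlap).

    Used to quantify e.g. accessibility (ATAC peak signal) within stitched
    enhancer regions.  Returns one replicate-signal vector per enhancer.
    """
    if peaks:
        n_reps = {len(np.atleast_1d(p.signal_by_replicate)) for p in peaks}
        if len(n_reps) > 1:
            raise ValueError("inconsistent replicate counts across peaks")
        n_rep = n_reps.pop()
    else:
        n_rep = 1
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, pk in enumerate(peaks):
        iv = _as_interval(pk)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for enh in enhancers:
        iv = _as_interval(enh)
        total = np.zeros(n_rep)
        for start, end, j in by_chrom.get(iv.chrom, []):
            if start >= iv.end:
                break
            if end > iv.start:
                total += np.asarray(peaks[j].signal_by_replicate, dtype=float)
        out.append(total)
    return out


def gene_profiles(
    assignments: Mapping[str, Sequence[StitchedEnhancer]],
    tf_peaks: Sequence = (),
    paired_end: bool = True,
) -> pd.DataFrame:
    """Per-(gene, enhancer-class) occupancy profile table.

    Columns: gene_id, enhancer_class (SE/TE), n_enhancers, mean_enhancer_bp,
    reads_per_gene, reads_per_kb_per_enhancer, sites_per_gene,
    sites_per_kb_per_enhancer.
    """
    tf_list = list(tf_peaks)
    rows = []
    for gene_id, enhancers in assignments.items():
        for cls in ("SE", "TE"):
            subset = [e for e in enhancers if e.enhancer_class == cls]
            if not subset:
                continue
            lengths = [e.length for e in subset]
            reads = reads_per_gene(subset, paired_end=paired_end)
            uniq_sites, per_enh_sites = sites_per_gene(subset, tf_list)
            rows.append(
                {
                    "gene_id": gene_id,
                    "enhancer_class": cls,
                    "n_enhancers": len(subset),
                    "mean_enhancer_bp": float(np.mean(lengths)),
                    "reads_per_gene": reads,
                    "reads_per_kb_per_enhancer": normalize_per_enhancer(reads, lengths),
                    "sites_per_gene": uniq_sites,
                    "sites_per_kb_per_enhancer": normalize_per_enhancer(
                        float(per_enh_sites), lengths
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "enhancer_class",
            "n_enhancers",
            "mean_enhancer_bp",
            "reads_per_gene",
            "reads_per_kb_per_enhancer",
            "sites_per_gene",
            "sites_per_kb_per_enhancer",
        ],
    )


def binned_pearson(
    track_a: CoverageTrack, track_b: CoverageTrack, bin_size: int = 10_000
) -> float:
    """Pearson correlation of two coverage tracks over fixed genomic bins."""
    if track_a.chrom_sizes != track_b.chrom_sizes:
        raise ValueError("tracks have different chromosome-size tables")
    a = track_a.rebin(bin_size).concatenated()
    b = track_b.rebin(bin_size).concatenated()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance track: Pearson correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def tss_meta_profile(
    track: CoverageTrack,
    tss_list: Sequence[tuple[str, int, str]],
    half_window: int = 2_000,
) -> np.ndarray:
    """Mean read depth per base offset from the TSS, strand-aware.

    ``tss_list`` holds (chrom, position, strand) triples; minus-strand
    profiles are reversed before averaging so positive offsets always point
    downstream.  Positions clipped by chromosome ends contribute only their
    in-bounds offsets.  Returns a vector of length ``2 * half_window + 1``
    for offsets ``-half_window .. +half_window``.
    """
    if len(tss_list) == 0:
        raise ValueError("empty TSS list")
    offsets = np.arange(-half_window, half_window + 1)
    profiles = np.full((len(tss_list), len(offsets)), np.nan)
    for i, (chrom, pos, strand) in enumerate(tss_list):
        values = track.value_at(chrom, pos + offsets)
        if strand == "-":
            values = values[::-1]
        profiles[i] = values
    return np.nanmean(profiles, axis=0)


REDUCTION_BANDS = ("<0", "0-19", "20-39", "40-59", "60-79", "80-99", "100")


def _band(reduction: float) -> str:
    if reduction < 0:
        return "<0"
    if reduction >= 100:
        return "100"
    edges = [0, 20, 40, 60, 80, 100]
    labels = ["0-19", "20-39", "40-59", "60-79", "80-99"]
    for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
        if lo <= reduction < hi:
            return lab
    raise AssertionError("unreachable")


def knockout_contrast(
    profiles_wt: Mapping[str, float],
    profiles_ko: Mapping[str, float],
    classes: Mapping[str, str] | None = None,
    wt_floor: float = 1.0,
) -> dict:
    """Percent signal reduction per gene and per class.

    ``reduction = (WT - KO) / WT * 100`` for genes with WT signal above
    ``wt_floor`` (RPM); genes below the floor are excluded from class
    medians and reported in ``n_excluded``.  Class summaries give the median
    reduction and counts per banding
    ``{<0, 0-19, 20-39, 40-59, 60-79, 80-99, 100}``.
    """
    if set(profiles_wt) != set(profiles_ko):
        raise ValueError("WT and KO profiles cover different gene sets")
    per_gene: dict[str, float] = {}
    n_excluded = 0
    for gene, wt in profiles_wt.items():
        if wt <= 0 or wt < wt_floor:
            n_excluded += 1
            continue
        per_gene[gene] = (wt - profiles_ko[gene]) / wt * 100.0

    summaries: dict[str, dict] = {}
    groups: dict[str, list[float]] = {}
    for gene, red in per_gene.items():
        cls = classes.get(gene, "all") if classes else "all"
        groups.setdefault(cls, []).append(red)
    for cls, values in groups.items():
        bands = {b: 0 for b in REDUCTION_BANDS}
        for v in values:
            bands[_band(v)] += 1
        summaries[cls] = {
            "n": len(values),
            "median_reduction_pct": float(np.median(values)),
            "bands": bands,
        }
    return {"per_gene": per_gene, "by_class": summaries, "n_excluded": n_excluded}
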