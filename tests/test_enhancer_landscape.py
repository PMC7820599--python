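"""Enhancer definition, stitching, inflection-point SE calling, annotation."""

import numpy as np
import pytest

from superchrom import (
    GeneModel,
    GenomicInterval,
    SignalPeak,
    StitchingParams,
    annotate_genomic_distribution,
    call_super_enhancers,
    define_potential_enhancers,
    stitch,
)
from superchrom.enhancer_landscape import _inflection_threshold

from conftest import as_peaks, mask_union, random_intervals


def peak(chrom, start, end, signal=(10.0,)):
    return SignalPeak(GenomicInterval(chrom, start, end), signal)


class TestPotentialEnhancers:
    def test_k27ac_with_k4me1_cover_retained(self):
        k27 = [peak("chr1", 100, 600)]
        assert define_potential_enhancers(k27, [peak("chr1", 550, 900)]) == k27

    def test_k27ac_without_k4me1_dropped(self):
        k27 = [peak("chr1", 100, 600)]
        assert define_potential_enhancers(k27, [peak("chr1", 5_000, 5_500)]) == []

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty H3K27ac"):
            assert define_potential_enhancers([], [peak("chr1", 1, 2)]) == []

    def test_matches_mask_oracle(self, rng):
        k27 = as_peaks(random_intervals(rng, 200))
        k4 = as_peaks(random_intervals(rng, 200))
        masks = mask_union([p.interval for p in k4], ["chr1", "chr2"], 11_000)
        expected = [
            p for p in k27 if masks[p.interval.chrom][p.interval.start : p.interval.end].any()
        ]
        assert define_potential_enhancers(k27, k4) == expected


def union_find_stitch_oracle(peaks, tss_by_chrom, distance, exclusion):
    """Brute-force transitive closure over pairwise gap <= distance."""
    kept = []
    for pk in peaks:
        iv = pk.interval
        contained = any(
            tss - exclusion <= iv.start and iv.end <= tss + exclusion
            for tss in tss_by_chrom.get(iv.chrom, [])
        )
        if not contained:
            kept.append(pk)
    parent = list(range(len(kept)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i].interval, kept[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= distance:
                parent[find(i)] = find(j)
    clusters = {}
    for i, pk in enumerate(kept):
        clusters.setdefault(find(i), []).append(pk)
    return {
        frozenset((p.interval.chrom, p.interval.start, p.interval.end) for p in c)
        for c in clusters.values()
    }


class TestStitch:
    def test_gap_below_threshold_merges(self):
        peaks = [peak("chr1", 1_000, 2_000), peak("chr1", 14_000, 15_000)]
        (enh,) = stitch(peaks, [])
        assert enh.interval == GenomicInterval("chr1", 1_000, 15_000)
        assert enh.signal_by_replicate[0] == 20.0

    def test_gap_above_threshold_splits(self):
        peaks = [peak("chr1", 1_000, 2_000), peak("chr1", 15_000, 16_000)]
        assert len(stitch(peaks, [])) == 2

    def test_tss_contained_peak_excluded(self):
        peaks = [peak("chr1", 99_000, 101_000)]
        assert stitch(peaks, [("chr1", 100_000)]) == []

    def test_tss_partial_overlap_survives(self):
        # extends beyond the exclusion window -> kept
        peaks = [peak("chr1", 99_000, 103_000)]
        assert len(stitch(peaks, [("chr1", 100_000)])) == 1

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            ivs = random_intervals(rng, 120, max_pos=200_000, max_len=3_000)
            peaks = as_peaks(ivs)
            tss = {
                "chr1": [int(rng.integers(0, 200_000)) for _ in range(5)],
                "chr2": [int(rng.integers(0, 200_000)) for _ in range(5)],
            }
            genes = [(c, t) for c, ts in tss.items() for t in ts]
            params = StitchingParams(stitch_distance=4_000, tss_exclusion=2_500)
            got = {
                frozenset(
                    (p.interval.chrom, p.interval.start, p.interval.end)
                    for p in e.constituent_peaks
                )
                for e in stitch(peaks, genes, params)
            }
            assert got == union_find_stitch_oracle(peaks, tss, 4_000, 2_500)

    def test_constituent_conservation_and_separation(self, rng):
        peaks = as_peaks(random_intervals(rng, 400, max_pos=500_000, max_len=2_000))
        enhancers = stitch(peaks, [])
        assert sum(len(e.constituent_peaks) for e in enhancers) == len(peaks)
        by_chrom = {}
        for e in enhancers:
            by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > 12_500

    def test_wider_stitch_distance_never_increases_count(self, rng):
        peaks = as_peaks(random_intervals(rng, 200, max_pos=300_000, max_len=2_000))
        counts = [
            len(stitch(peaks, [], StitchingParams(stitch_distance=d)))
            for d in (0, 2_000, 8_000, 20_000)
        ]
        assert counts == sorted(counts, reverse=True)


def make_stitched(signals):
    from superchrom.enhancer_landscape import StitchedEnhancer

    return [
        StitchedEnhancer(
            interval=GenomicInterval("chr1", 100_000 * i + 1, 100_000 * i + 1_000),
            constituent_peaks=[],
            signal_by_replicate=np.array([s]),
            enhancer_id=f"e{i}",
        )
        for i, s in enumerate(signals)
    ]


class TestInflectionCall:
    def test_quadratic_curve_analytic_tangent(self):
        signals = np.array([r**2 for r in range(1, 1_001)], dtype=float)
        threshold, rank = _inflection_threshold(signals)
        assert abs(rank - 500) <= 1
        n_super = int((signals > threshold).sum())
        assert abs(n_super - 500) <= 1

    def test_linear_curve_has_no_inflection(self):
        enhancers = make_stitched(np.arange(1.0, 101.0))
        with pytest.warns(UserWarning, match="no inflection"):
            ranked = call_super_enhancers(enhancers)
        assert sum(e.is_super for e in ranked) == 0

    def test_all_equal_signals_yield_zero_supers(self):
        enhancers = make_stitched(np.full(10, 5.0))
        with pytest.warns(UserWarning):
            ranked = call_super_enhancers(enhancers)
        assert sum(e.is_super for e in ranked) == 0

    def test_bimodal_separation(self):
        signals = np.concatenate([np.linspace(1, 20, 90), np.linspace(300, 400, 10)])
        ranked = call_super_enhancers(make_stitched(signals))
        supers = {e.enhancer_id for e in ranked if e.is_super}
        assert supers == {f"e{i}" for i in range(90, 100)}

    def test_label_invariant_to_input_order(self, rng):
        signals = rng.lognormal(2.5, 0.8, size=200)
        enhancers = make_stitched(signals)
        ranked_a = call_super_enhancers(list(enhancers))
        labels_a = {e.enhancer_id: e.is_super for e in ranked_a}
        order = rng.permutation(len(enhancers))
        shuffled = make_stitched(signals)
        ranked_b = call_super_enhancers([shuffled[i] for i in order])
        labels_b = {e.enhancer_id: e.is_super for e in ranked_b}
        assert labels_a == labels_b
        assert sorted(e.rank for e in ranked_b) == list(range(1, 201))

    def test_requires_three_enhancers(self):
        with pytest.raises(ValueError, match="at least 3"):
            call_super_enhancers(make_stitched([1.0, 2.0]))


class TestGenomicDistribution:
    @staticmethod
    def genes():
        return [
            GeneModel(
                "g1", GenomicInterval("chr1", 10_000, 40_000, "+"), tss=10_000,
                expression={"unstim": 50.0},
            )
        ]

    def test_promoter_category(self):
        enh = make_stitched([1.0])
        enh[0].interval = GenomicInterval("chr1", 10_100, 10_900)  # midpoint 500 bp away
        cats, props = annotate_genomic_distribution(enh, self.genes())
        assert cats == ["Promoter"]
        assert props["Promoter"] == 1.0

    def test_distal_intergenic_category(self):
        enh = make_stitched([1.0])
        enh[0].interval = GenomicInterval("chr1", 500_000, 501_000)
        cats, _ = annotate_genomic_distribution(enh, self.genes())
        assert cats == ["Distal Intergenic"]

    def test_exon_priority_over_intron(self):
        enh = make_stitched([1.0])
        enh[0].interval = GenomicInterval("chr1", 20_000, 21_000)
        exons = {"g1": [GenomicInterval("chr1", 20_400, 20_600)]}
        cats, _ = annotate_genomic_distribution(enh, self.genes(), exons=exons)
        assert cats == ["Exon"]
        cats, _ = annotate_genomic_distribution(enh, self.genes())
        assert cats == ["Intron"]  # gene-body fallback

    def test_matches_exhaustive_reclassification(self, rng, small_bundle):
        from superchrom import call_enhancer_landscape

        ranked = call_enhancer_landscape(
            small_bundle.k27ac, small_bundle.genes, small_bundle.k4me1
        )
        cats, props = annotate_genomic_distribution(ranked, small_bundle.genes)
        assert abs(sum(props.values()) - 1.0) < 1e-9
        window = 2_500
        for e, cat in zip(ranked, cats):
            mid = e.interval.midpoint
            near_tss = any(
                g.chrom == e.interval.chrom and abs(g.tss - mid) <= window
                for g in small_bundle.genes
            )
            in_body = any(
                g.chrom == e.interval.chrom
                and g.interval.start <= mid < g.interval.end
                for g in small_bundle.genes
            )
            expected = "Promoter" if near_tss else ("Intron" if in_body else "Distal Intergenic")
            assert cat == expected
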