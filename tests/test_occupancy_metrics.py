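"""Per-gene occupancy aggregation, correlation, profiles, KO contrasts."""

import numpy as np
import pytest

from superchrom import (
    CoverageTrack,
    GenomicInterval,
    SignalPeak,
    binned_pearson,
    knockout_contrast,
    normalize_per_enhancer,
    reads_per_gene,
    sites_per_gene,
    tss_meta_profile,
)
from superchrom.enhancer_landscape import StitchedEnhancer


def enh(start, end, signal, chrom="chr1", eid="e"):
    return StitchedEnhancer(
        interval=GenomicInterval(chrom, start, end),
        constituent_peaks=[],
        signal_by_replicate=np.asarray(signal, dtype=float),
        enhancer_id=eid,
    )


class TestReadsPerGene:
    def test_replicate_average_then_sum_then_halve(self):
        e1 = enh(1_000, 2_000, [100.0, 120.0], eid="E1")
        e2 = enh(20_000, 21_000, [50.0, 30.0], eid="E2")
        assert reads_per_gene([e1, e2]) == 75.0  # (110 + 40) / 2

    def test_no_enhancers_gives_zero(self):
        assert reads_per_gene([]) == 0.0

    def test_single_replicate_still_halved(self):
        assert reads_per_gene([enh(0, 1_000, [60.0])]) == 30.0

    def test_additive_over_disjoint_subsets(self):
        parts = [enh(i * 10_000, i * 10_000 + 500, [float(10 * i + 10)], eid=f"E{i}")
                 for i in range(6)]
        total = reads_per_gene(parts)
        assert abs(total - (reads_per_gene(parts[:3]) + reads_per_gene(parts[3:]))) < 1e-12

    def test_inconsistent_replicates_rejected(self):
        with pytest.raises(ValueError, match="E2"):
            reads_per_gene([enh(0, 1_000, [1.0, 2.0], eid="E1"),
                            enh(5_000, 6_000, [1.0], eid="E2")])


class TestDensities:
    def test_mean_length_normalization(self):
        assert normalize_per_enhancer(75.0, [2_000, 4_000]) == 25.0

    def test_unit_divisor(self):
        assert normalize_per_enhancer(42.0, [1_000]) == 42.0

    def test_doubling_lengths_halves_density(self):
        d1 = normalize_per_enhancer(10.0, [1_500, 2_500])
        d2 = normalize_per_enhancer(10.0, [3_000, 5_000])
        assert abs(d1 - 2 * d2) < 1e-12

    def test_zero_enhancers_reported_missing(self):
        assert normalize_per_enhancer(10.0, []) is None

    def test_duplicating_enhancers_preserves_density(self):
        e1, e2 = enh(0, 2_000, [40.0], eid="a"), enh(9_000, 11_000, [40.0], eid="b")
        reads = reads_per_gene([e1, e2])
        dens = normalize_per_enhancer(reads, [2_000, 2_000])
        reads_dup = reads_per_gene([e1, e2, e1, e2])
        dens_dup = normalize_per_enhancer(reads_dup, [2_000] * 4)
        assert abs(dens_dup - 2 * dens) < 1e-12  # reads double, mean length fixed
        # per-enhancer density (value per duplicated set) is scale-consistent


class TestBoundSites:
    def tf(self, start, end):
        return SignalPeak(GenomicInterval("chr1", start, end), (1.0,))

    def test_simple_count(self):
        enhancers = [enh(0, 5_000, [1.0], eid="a")]
        tf = [self.tf(100, 250), self.tf(1_000, 1_150), self.tf(4_800, 4_950)]
        assert sites_per_gene(enhancers, tf) == (3, 3)

    def test_straddling_peak_deduplicated_per_gene(self):
        enhancers = [enh(0, 1_000, [1.0], eid="a"), enh(1_000, 2_000, [1.0], eid="b")]
        tf = [self.tf(900, 1_100)]  # spans both enhancers
        unique, per_enh = sites_per_gene(enhancers, tf)
        assert unique == 1 and per_enh == 2

    def test_outside_peaks_ignored(self):
        assert sites_per_gene([enh(0, 1_000, [1.0])], [self.tf(5_000, 5_100)]) == (0, 0)


class TestBinnedPearson:
    def make_track(self, values, bin_size=1_000):
        sizes = {"chr1": len(values) * bin_size}
        return CoverageTrack(sizes, bin_size, {"chr1": np.asarray(values, float)})

    def test_self_correlation_is_one(self, rng):
        v = rng.random(50)
        assert binned_pearson(self.make_track(v), self.make_track(v)) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        v = rng.random(50)
        r = binned_pearson(self.make_track(v), self.make_track(2 * v))
        assert r == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self, rng):
        a, b = rng.random(300), rng.random(300)
        r = binned_pearson(self.make_track(a), self.make_track(b), bin_size=10_000)
        # textbook formula on the rebinned vectors
        ar = a.reshape(-1, 10).sum(axis=1)
        br = b.reshape(-1, 10).sum(axis=1)
        expected = ((ar - ar.mean()) * (br - br.mean())).sum() / (
            np.sqrt(((ar - ar.mean()) ** 2).sum() * ((br - br.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        flat = self.make_track(np.ones(20))
        bumpy = self.make_track(np.arange(20.0))
        with pytest.raises(ValueError, match="zero-variance"):
            binned_pearson(flat, bumpy)

    def test_mismatched_chromosomes_rejected(self):
        a = self.make_track(np.arange(10.0))
        b = CoverageTrack({"chr2": 10_000}, 1_000)
        with pytest.raises(ValueError, match="chromosome"):
            binned_pearson(a, b)


class TestTssMetaProfile:
    def test_impulse_coverage_gives_delta_at_zero(self):
        sizes = {"chr1": 10_000}
        track = CoverageTrack(sizes, bin_size=1)
        tss_list = [("chr1", 2_000, "+"), ("chr1", 7_000, "-")]
        for chrom, pos, _ in tss_list:
            track.data[chrom][pos] = 5.0
        profile = tss_meta_profile(track, tss_list, half_window=100)
        assert profile[100] == 5.0
        assert np.all(profile[:100] == 0) and np.all(profile[101:] == 0)

    def test_uniform_coverage_is_flat(self):
        track = CoverageTrack({"chr1": 5_000}, 1, {"chr1": np.full(5_000, 2.0)})
        profile = tss_meta_profile(track, [("chr1", 2_500, "+")], half_window=50)
        assert np.all(profile == 2.0)

    def test_matches_naive_per_tss_extraction(self, rng):
        data = rng.random(20_000)
        track = CoverageTrack({"chr1": 20_000}, 1, {"chr1": data})
        tss_list = [("chr1", int(p), s) for p, s in
                    zip(rng.integers(300, 19_700, 25), rng.choice(["+", "-"], 25))]
        w = 200
        profile = tss_meta_profile(track, tss_list, half_window=w)
        rows = []
        for chrom, pos, strand in tss_list:
            vals = data[pos - w : pos + w + 1]
            rows.append(vals[::-1] if strand == "-" else vals)
        np.testing.assert_allclose(profile, np.mean(rows, axis=0))

    def test_minus_strand_profiles_are_reversed(self):
        data = np.zeros(1_000)
        data[510] = 1.0  # 10 bp downstream on + strand
        track = CoverageTrack({"chr1": 1_000}, 1, {"chr1": data})
        plus = tss_meta_profile(track, [("chr1", 500, "+")], half_window=20)
        minus = tss_meta_profile(track, [("chr1", 500, "-")], half_window=20)
        assert plus[30] == 1.0 and minus[10] == 1.0

    def test_empty_tss_list_rejected(self):
        track = CoverageTrack({"chr1": 1_000}, 1)
        with pytest.raises(ValueError, match="empty TSS"):
            tss_meta_profile(track, [], half_window=10)


class TestKnockoutContrast:
    def test_percent_reduction_arithmetic(self):
        out = knockout_contrast({"g": 100.0}, {"g": 33.0})
        assert out["per_gene"]["g"] == pytest.approx(67.0)

    def test_no_change_is_zero(self):
        out = knockout_contrast({"g": 50.0}, {"g": 50.0})
        assert out["per_gene"]["g"] == 0.0

    def test_class_medians_and_bands(self):
        wt = {f"g{i}": 100.0 for i in range(5)}
        ko = {"g0": 110.0, "g1": 90.0, "g2": 55.0, "g3": 10.0, "g4": 0.0}
        out = knockout_contrast(wt, ko, classes={g: "SE" for g in wt})
        summary = out["by_class"]["SE"]
        assert summary["median_reduction_pct"] == pytest.approx(45.0)
        assert summary["bands"] == {
            "<0": 1, "0-19": 1, "20-39": 0, "40-59": 1, "60-79": 0, "80-99": 1, "100": 1,
        }

    def test_low_wt_genes_excluded_with_count(self):
        out = knockout_contrast({"a": 0.5, "b": 10.0}, {"a": 0.1, "b": 5.0})
        assert "a" not in out["per_gene"] and out["n_excluded"] == 1

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="different gene sets"):
            knockout_contrast({"a": 1.0}, {"b": 1.0})
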