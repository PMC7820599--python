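"""Regulatory domains, enhancer-gene assignment, regulatory potential."""

import math

import numpy as np
import pytest

from superchrom import (
    GeneModel,
    GenomicInterval,
    assign_enhancers,
    build_regulatory_domains,
    regulatory_potential,
    regulatory_potential_table,
)

from conftest import random_intervals


def gene(gene_id, tss, strand="+", chrom="chr1", expr=100.0):
    if strand == "+":
        body = GenomicInterval(chrom, tss, tss + 10_000, strand)
    else:
        body = GenomicInterval(chrom, max(0, tss - 10_000), tss, strand)
    return GeneModel(gene_id, body, tss=tss, expression={"unstim": expr})


class TestRegulatoryDomains:
    def test_extension_truncated_at_neighbor_basal(self):
        a, b = gene("A", 100_000), gene("B", 160_000)
        dom_a, dom_b = build_regulatory_domains([a, b])
        assert (dom_a.basal.start, dom_a.basal.end) == (95_000, 101_000)
        assert (dom_b.basal.start, dom_b.basal.end) == (155_000, 161_000)
        assert dom_a.extended.end == 155_000  # truncated by B's basal, not 201 kb
        assert dom_b.extended.start == 101_000

    def test_isolated_gene_full_extension(self):
        (dom,) = build_regulatory_domains([gene("A", 500_000)])
        assert dom.extended.start == dom.basal.start - 100_000
        assert dom.extended.end == dom.basal.end + 100_000

    def test_minus_strand_basal_mirrored(self):
        (dom,) = build_regulatory_domains([gene("A", 100_000, strand="-")])
        assert (dom.basal.start, dom.basal.end) == (99_000, 105_000)

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_regulatory_domains([gene("A", 100_000), gene("A", 300_000)])

    def test_mirror_symmetry(self):
        """Reversing strands and mirroring coordinates mirrors the domains."""
        size = 1_000_000
        genes_fwd = [gene("A", 100_000, "+"), gene("B", 160_000, "-")]
        genes_rev = [
            GeneModel(
                g.gene_id,
                GenomicInterval(
                    g.chrom, size - g.interval.end, size - g.interval.start,
                    "-" if g.strand == "+" else "+",
                ),
                tss=size - g.tss,
                expression=g.expression,
            )
            for g in genes_fwd
        ]
        sizes = {"chr1": size}
        doms_f = {d.gene_id: d for d in build_regulatory_domains(genes_fwd, chrom_sizes=sizes)}
        doms_r = {d.gene_id: d for d in build_regulatory_domains(genes_rev, chrom_sizes=sizes)}
        for gid in doms_f:
            assert doms_r[gid].basal.start == size - doms_f[gid].basal.end
            assert doms_r[gid].extended.end == size - doms_f[gid].extended.start


class TestAssignment:
    def test_intergenic_region_falls_in_both_flanking_domains(self):
        # both domains cover the shared gap (basal-plus-extension semantics:
        # each extension reaches the neighbour's basal domain)
        a, b = gene("A", 100_000), gene("B", 160_000)
        domains = build_regulatory_domains([a, b])
        region = [GenomicInterval("chr1", 150_000, 151_000)]
        asg = assign_enhancers(region, domains, [a, b], "unstim")
        assert asg["A"] == region and asg["B"] == region

    def test_region_beyond_neighbor_basal_is_exclusive(self):
        # a region inside B's basal domain is out of reach of A's extension
        a, b = gene("A", 100_000), gene("B", 160_000)
        domains = build_regulatory_domains([a, b])
        region = [GenomicInterval("chr1", 156_000, 157_000)]
        asg = assign_enhancers(region, domains, [a, b], "unstim")
        assert asg["A"] == [] and asg["B"] == region

    def test_expression_filter_is_strict(self):
        low = gene("L", 100_000, expr=29.5)
        exact = gene("E", 400_000, expr=30.0)
        hi = gene("H", 700_000, expr=30.5)
        genes = [low, exact, hi]
        domains = build_regulatory_domains(genes)
        regions = [GenomicInterval("chr1", t - 20_000, t - 19_000) for t in
                   (100_000, 400_000, 700_000)]
        asg = assign_enhancers(regions, domains, genes, "unstim")
        assert "L" not in asg and "E" not in asg  # "higher than 30" only
        assert asg["H"] == [regions[2]]

    def test_enhancer_in_two_domains_assigned_to_both(self):
        a, b = gene("A", 100_000), gene("B", 130_000)
        domains = build_regulatory_domains([a, b])
        # inside A's extension and overlapping B's basal
        region = [GenomicInterval("chr1", 124_000, 126_000)]
        asg = assign_enhancers(region, domains, [a, b], "unstim")
        assert asg["A"] == region and asg["B"] == region

    def test_matches_all_pairs_brute_force(self, rng):
        genes = []
        positions = np.sort(rng.choice(np.arange(20_000, 2_000_000, 15_000), 40, False))
        for i, tss in enumerate(positions):
            genes.append(
                gene(f"g{i}", int(tss), strand="+" if rng.random() < 0.5 else "-",
                     expr=float(rng.uniform(0, 100)))
            )
        domains = build_regulatory_domains(genes)
        regions = random_intervals(rng, 500, chroms=("chr1",), max_pos=2_100_000,
                                   max_len=5_000)
        asg = assign_enhancers(regions, domains, genes, "unstim")
        dom_by_id = {d.gene_id: d for d in domains}
        for g in genes:
            if not g.expression["unstim"] > 30.0:
                assert g.gene_id not in asg
                continue
            ext = dom_by_id[g.gene_id].extended
            expected = {r for r in regions if r.overlaps(ext)}
            assert set(asg[g.gene_id]) == expected


class TestRegulatoryPotential:
    @pytest.mark.parametrize(
        "offset, expected",
        [(0, math.exp(-0.5)), (50_000, math.exp(-2.5)), (100_000, math.exp(-4.5))],
    )
    def test_closed_form(self, offset, expected):
        tss = 1_000_000
        pk = GenomicInterval("chr1", tss + offset - 100, tss + offset + 100)
        rp = regulatory_potential(tss, [pk])
        assert abs(rp.score - expected) < 1e-9

    def test_zero_beyond_window(self):
        tss = 1_000_000
        pk = GenomicInterval("chr1", tss + 100_001 - 50, tss + 100_001 + 50)
        rp = regulatory_potential(tss, [pk])
        assert rp.score == 0.0 and rp.n_peaks == 0

    def test_additive_and_distance_decreasing(self):
        tss = 1_000_000
        near = GenomicInterval("chr1", tss + 9_900, tss + 10_100)
        far = GenomicInterval("chr1", tss + 79_900, tss + 80_100)
        s_near = regulatory_potential(tss, [near]).score
        s_far = regulatory_potential(tss, [far]).score
        assert s_near > s_far > 0
        both = regulatory_potential(tss, [near, far]).score
        assert abs(both - (s_near + s_far)) < 1e-12

    def test_edge_mode_uses_nearest_edge(self):
        tss = 1_000_000
        pk = GenomicInterval("chr1", tss + 10_000, tss + 30_000)  # centre at 20 kb
        centre = regulatory_potential(tss, [pk], distance_mode="center").score
        edge = regulatory_potential(tss, [pk], distance_mode="edge").score
        assert abs(centre - math.exp(-(0.5 + 4 * 0.2))) < 1e-9
        assert abs(edge - math.exp(-(0.5 + 4 * 0.1))) < 1e-9

    def test_table_matches_scalar_routine(self, rng):
        genes = [gene(f"g{i}", int(t)) for i, t in
                 enumerate(np.sort(rng.choice(np.arange(10_000, 900_000, 20_000), 20, False)))]
        peaks = random_intervals(rng, 200, chroms=("chr1",), max_pos=1_000_000)
        table = regulatory_potential_table(genes, peaks).set_index("gene_id")
        for g in genes:
            rp = regulatory_potential(g.tss, peaks, chrom=g.chrom)
            assert abs(table.loc[g.gene_id, "rp_score"] - rp.score) < 1e-9
            assert table.loc[g.gene_id, "n_peaks"] == rp.n_peaks
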