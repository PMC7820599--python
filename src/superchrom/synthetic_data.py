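"""Ground-truth synthetic chromatin landscapes.

The generator emits a complete file bundle -- gene table, H3K27ac / H3K4me1 /
ATAC / GATA2 peak BEDs with two replicate signal columns, a genome FASTA
with planted motif occurrences, expression tables and ATAC coverage
bedGraphs -- whose statistical structure mirrors the mast-cell study design
the analysis modules target:

* two enhancer classes: isolated typical enhancers (TE, log-normal length,
  median 1 kb) and super-enhancer clusters (SE) of 5-15 constituent peaks
  with intra-cluster gaps well below the stitch distance, spanning ~13x the
  TE length;
* identity (ID) genes carry SEs with probability 0.36 versus 0.043 for
  non-ID expressed genes;
* GATA2-bound sites planted at 1.9x per-kb density inside SEs, and GATA
  motif occurrences at 3x per-gene frequency in SE accessible regions;
* expression coupled to enhancer regulatory potential
  (log FPKM = a + b*S_g + noise);
* a knockout perturbation scaling accessibility / H3K4me1 / H3K27ac and
  key-ID mRNA by the configured class-specific reductions, and an
  activation perturbation scaling H3K27ac and accessibility (never H3K4me1)
  at induced genes' enhancers.

Geometry note: weakly-expressed "silent" genes without enhancers are
interleaved between expressed genes.  Their basal domains truncate the
neighbouring GREAT extensions, so every planted enhancer falls inside
exactly one expressed gene's regulatory domain and planted per-gene labels
are unambiguous.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome_model import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    SignalPeak,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gene_table,
)
from .gene_linking import regulatory_potential

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "LandscapeBundle",
    "generate_landscape",
    "apply_knockout",
    "apply_activation",
    "DEFAULT_KO_REDUCTIONS",
    "DEFAULT_ACTIVATION_FOLDS",
]

# class-specific fractional signal reductions after loss of GATA2
DEFAULT_KO_REDUCTIONS: dict = {
    "atac": {"SE": 0.67, "TE": 0.23},
    "k4me1": {"TE": 0.37, "SE": 0.40},
    "k27ac": {"TE": 0.43, "SE": 0.51},
    "mrna_key_id": 0.44,
}

# fold increases after IgE receptor crosslinking (H3K4me1 never changes)
DEFAULT_ACTIVATION_FOLDS: dict = {
    "k27ac": {"SE": 3.0, "TE": 1.5},
    "atac": {"SE": 1.7, "TE": 1.5},
}

_GATA_WORDS = ("AAGATAAA", "AAGATAAG", "ATGATAAA", "ATGATAAG")
_MITF_WORD = "TCACGTGA"


@dataclass
class LandscapeConfig:
    """All generator knobs; the defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 500
    id_gene_fraction: float = 0.2
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    # enhancer geometry
    te_length_median: float = 1_000.0
    te_length_sigma: float = 0.3
    se_length_multiplier: float = 13.0
    se_peaks_min: int = 5
    se_peaks_max: int = 15
    # class frequencies
    p_se_given_id: float = 0.36
    p_se_given_non_id: float = 0.043
    # GATA2 occupancy and motif structure
    gata_site_density_te: float = 1.0  # bound sites per kb at TEs
    gata_site_density_fold_se: float = 1.9
    motif_mean_te: float = 2.0  # planted GATA motifs per gene at TEs
    motif_fold_se: float = 3.0
    mitf_motif_mean: float = 1.0  # class-independent control motif
    # expression coupling: log FPKM = a + b * S_g + N(0, sigma)
    expr_intercept: float = 2.0
    expr_slope: float = 3.0
    expr_sigma: float = 0.5
    # activation
    induced_fraction: float = 0.2
    induced_fold: float = 4.0
    highly_induced_fold: float = 15.0
    highly_induced_subfraction: float = 0.25
    # signal levels (RPM) and noise
    n_replicates: int = 2
    replicate_sigma: float = 0.1
    te_signal_median: float = 15.0
    te_signal_sigma: float = 0.3
    se_peak_signal_median: float = 30.0
    se_peak_signal_sigma: float = 0.3
    k4me1_signal_median: float = 8.0
    atac_signal_median: float = 6.0
    promoter_atac_signal_median: float = 8.0
    promoter_k27ac_signal_median: float = 12.0
    gata_signal_median: float = 5.0
    promoter_peak_fraction: float = 0.5
    n_distractor_k27ac: int = 30  # H3K27ac peaks without H3K4me1 cover
    # perturbations
    ko_reductions: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_KO_REDUCTIONS)))
    ko_jitter_sigma: float = 0.03
    activation_folds: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_ACTIVATION_FOLDS)))
    coverage_bin: int = 200

    def validate(self) -> None:
        for name in ("id_gene_fraction", "p_se_given_id", "p_se_given_non_id",
                     "induced_fraction", "highly_induced_subfraction",
                     "promoter_peak_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for mark, by_class in self.ko_reductions.items():
            if mark == "mrna_key_id":
                if not 0 <= by_class <= 1:
                    raise ValueError("mrna_key_id reduction outside [0, 1]")
                continue
            for cls, red in by_class.items():
                if not 0 <= red <= 1:
                    raise ValueError(f"ko reduction {mark}/{cls}={red} outside [0, 1]")
        if self.se_length_multiplier <= 0 or self.motif_fold_se <= 0:
            raise ValueError("fold parameters must be positive")


@dataclass
class GroundTruth:
    """Planted labels, consistent with the emitted files."""

    # per planted (stitchable) enhancer, keyed "chrom:start-end" of its span
    enhancer_class: dict = field(default_factory=dict)  # key -> "SE" | "TE"
    enhancer_gene: dict = field(default_factory=dict)  # key -> owning gene_id
    planted_sites: dict = field(default_factory=dict)  # key -> GATA2 site count
    # per gene
    expressed_genes: list = field(default_factory=list)
    id_genes: list = field(default_factory=list)
    se_genes: list = field(default_factory=list)  # genes drawn to carry an SE
    induced_genes: list = field(default_factory=list)  # pass the FPKM filter
    planted_induction_fold: dict = field(default_factory=dict)
    planted_motifs: dict = field(default_factory=dict)  # gene -> {"SE": n, "TE": n}
    # perturbation parameters actually applied
    ko_reductions: dict = field(default_factory=dict)
    activation_folds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _span_key(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class LandscapeBundle:
    config: LandscapeConfig
    genes: list
    k27ac: list
    k4me1: list
    atac: list
    gata2: list
    sequences: dict
    truth: GroundTruth
    condition: str = "unstim"

    @property
    def chrom_sizes(self) -> dict:
        return dict(self.config.chrom_sizes)

    def atac_coverage(self, replicate: int) -> CoverageTrack:
        track = CoverageTrack(self.chrom_sizes, bin_size=self.config.coverage_bin)
        for pk in self.atac:
            track.add_interval(pk.interval, pk.signal_by_replicate[replicate])
        return track

    def expression(self, condition: str) -> dict:
        return {g.gene_id: g.expression[condition] for g in self.genes}

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.genes, out / "genes.tsv")
        write_bed(self.k27ac, out / "h3k27ac.bed")
        write_bed(self.k4me1, out / "h3k4me1.bed")
        write_bed(self.atac, out / "atac.bed")
        write_bed(self.gata2, out / "gata2.bed")
        write_fasta(self.sequences, out / "genome.fa")
        for r in range(self.config.n_replicates):
            write_bedgraph(self.atac_coverage(r), out / f"atac_rep{r + 1}.bedGraph")
        self.truth.to_json(out / "ground_truth.json")
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return median * np.exp(rng.normal(0.0, sigma, size=size))


def _replicated(rng: np.random.Generator, base: float, n_reps: int, sigma: float):
    return tuple(float(base * np.exp(rng.normal(0.0, sigma))) for _ in range(n_reps))


class _Builder:
    """Incremental peak-list builder bound to one RNG."""

    def __init__(self, cfg: LandscapeConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.k27ac: list[SignalPeak] = []
        self.k4me1: list[SignalPeak] = []
        self.atac: list[SignalPeak] = []
        self.gata2: list[SignalPeak] = []

    def add_k27ac(self, iv: GenomicInterval, median: float, with_k4me1: bool = True) -> None:
        cfg, rng = self.cfg, self.rng
        base = float(_lognormal(rng, median, cfg.te_signal_sigma))
        self.k27ac.append(
            SignalPeak(iv, _replicated(rng, base, cfg.n_replicates, cfg.replicate_sigma),
                       source_mark="H3K27ac")
        )
        if with_k4me1:
            cover = GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.end + 200)
            b4 = float(_lognormal(rng, cfg.k4me1_signal_median, cfg.te_signal_sigma))
            self.k4me1.append(
                SignalPeak(cover, _replicated(rng, b4, cfg.n_replicates, cfg.replicate_sigma),
                           source_mark="H3K4me1")
            )

    def add_atac(self, iv: GenomicInterval, median: float) -> None:
        cfg, rng = self.cfg, self.rng
        base = float(_lognormal(rng, median, cfg.te_signal_sigma))
        self.atac.append(
            SignalPeak(iv, _replicated(rng, base, cfg.n_replicates, cfg.replicate_sigma),
                       source_mark="ATAC")
        )

    def add_gata2_sites(self, span: GenomicInterval, density_per_kb: float) -> int:
        cfg, rng = self.cfg, self.rng
        lam = density_per_kb * len(span) / 1000.0
        n = int(rng.poisson(lam))
        n = min(n, max(1, len(span) // 200))  # cannot pack more 150-bp sites
        for _ in range(n):
            start = int(rng.integers(span.start, max(span.start + 1, span.end - 150)))
            base = float(_lognormal(rng, cfg.gata_signal_median, cfg.te_signal_sigma))
            self.gata2.append(
                SignalPeak(GenomicInterval(span.chrom, start, start + 150),
                           _replicated(rng, base, cfg.n_replicates, cfg.replicate_sigma),
                           source_mark="GATA2")
            )
        return n


def _se_cluster(cfg: LandscapeConfig, rng: np.random.Generator, chrom: str,
                anchor: int, side: int) -> list[GenomicInterval]:
    """Constituent peak intervals of one SE cluster, gaps < stitch distance."""
    n_pk = int(rng.integers(cfg.se_peaks_min, cfg.se_peaks_max + 1))
    span = float(_lognormal(rng, cfg.se_length_multiplier * cfg.te_length_median, 0.15))
    lens = _lognormal(rng, 800.0, 0.25, size=n_pk)
    total_len = lens.sum()
    if total_len > 0.85 * span:
        lens *= 0.85 * span / total_len
        total_len = lens.sum()
    gap_budget = span - total_len
    gaps = rng.dirichlet(np.ones(max(n_pk - 1, 1))) * gap_budget if n_pk > 1 else np.array([])
    gaps = np.minimum(gaps, 12_000.0)
    start = anchor if side > 0 else anchor - int(round(span))
    ivs = []
    pos = float(start)
    for i in range(n_pk):
        end = pos + max(lens[i], 150.0)
        ivs.append(GenomicInterval(chrom, int(round(pos)), int(round(end))))
        if i < n_pk - 1:
            pos = end + max(gaps[i], 100.0)
    return ivs


def generate_landscape(config: LandscapeConfig | None = None, seed: int | None = None) -> LandscapeBundle:
    """Generate a complete resting-state landscape bundle with ground truth."""
    cfg = config or LandscapeConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(
        ko_reductions=json.loads(json.dumps(cfg.ko_reductions)),
        activation_folds=json.loads(json.dumps(cfg.activation_folds)),
    )
    builder = _Builder(cfg, rng)

    # --- gene placement: alternate expressed / silent along each chromosome
    total_size = sum(cfg.chrom_sizes.values())
    chrom_names = sorted(cfg.chrom_sizes)
    genes_per_chrom = {
        c: max(2, int(round(cfg.n_genes * cfg.chrom_sizes[c] / total_size)))
        for c in chrom_names
    }
    placements = []  # (gene_id, chrom, tss, strand, body, expressed)
    gid = 0
    for chrom in chrom_names:
        size = cfg.chrom_sizes[chrom]
        n_c = genes_per_chrom[chrom]
        slot = size // n_c
        if slot < 45_000:
            raise ValueError(
                f"{chrom} too small for {n_c} genes: {slot} bp per gene slot "
                "(need >= 45 kb)"
            )
        for i in range(n_c):
            gid += 1
            tss = slot * i + slot // 2 + int(rng.integers(-1_000, 1_001))
            strand = "+" if rng.random() < 0.5 else "-"
            body_len = int(rng.integers(10_000, 30_001))
            if strand == "+":
                body = GenomicInterval(chrom, tss, min(tss + body_len, size), strand)
            else:
                body = GenomicInterval(chrom, max(0, tss - body_len), tss, strand)
            expressed = i % 2 == 0
            placements.append((f"gene_{gid:04d}", chrom, tss, strand, body, expressed))

    expressed_ids = [p[0] for p in placements if p[5]]
    n_id = int(round(cfg.id_gene_fraction * len(expressed_ids)))
    id_set = set(rng.choice(expressed_ids, size=n_id, replace=False)) if n_id else set()

    # --- enhancers, occupancy, motif bookkeeping
    own_k27_peaks: dict[str, list[SignalPeak]] = {}
    motif_plan: list[tuple[str, str, GenomicInterval, int]] = []  # gene, class, atac iv, n motifs
    se_density = cfg.gata_site_density_te * cfg.gata_site_density_fold_se

    for gene_id, chrom, tss, strand, body, expressed in placements:
        if not expressed:
            continue
        own_k27_peaks[gene_id] = []
        has_se = rng.random() < (cfg.p_se_given_id if gene_id in id_set else cfg.p_se_given_non_id)
        se_side = 1 if rng.random() < 0.5 else -1

        if has_se:
            truth.se_genes.append(gene_id)
            anchor = tss + se_side * int(rng.integers(5_000, 8_001))
            constituents = _se_cluster(cfg, rng, chrom, anchor, se_side)
            span = GenomicInterval(chrom, constituents[0].start, constituents[-1].end)
            key = _span_key(span)
            truth.enhancer_class[key] = "SE"
            truth.enhancer_gene[key] = gene_id
            se_atac_ivs = []
            for iv in constituents:
                builder.add_k27ac(iv, cfg.se_peak_signal_median)
                own_k27_peaks[gene_id].append(builder.k27ac[-1])
                mid = iv.midpoint
                atac_iv = GenomicInterval(chrom, max(iv.start, mid - 150), min(iv.end, mid + 150))
                builder.add_atac(atac_iv, cfg.atac_signal_median)
                se_atac_ivs.append(atac_iv)
            truth.planted_sites[key] = builder.add_gata2_sites(span, se_density)
            n_motifs = int(rng.poisson(cfg.motif_mean_te * cfg.motif_fold_se))
            motif_plan.append((gene_id, "SE", se_atac_ivs, n_motifs))

        # one typical enhancer per expressed gene, on the side away from the SE
        te_side = -se_side if has_se else (1 if rng.random() < 0.5 else -1)
        te_len = int(round(_lognormal(rng, cfg.te_length_median, cfg.te_length_sigma)))
        te_len = max(te_len, 300)
        d = int(rng.integers(8_500, 13_001)) if has_se else int(rng.integers(4_000, 13_001))
        if te_side > 0:
            te_iv = GenomicInterval(chrom, tss + d, tss + d + te_len)
        else:
            te_iv = GenomicInterval(chrom, tss - d - te_len, tss - d)
        key = _span_key(te_iv)
        truth.enhancer_class[key] = "TE"
        truth.enhancer_gene[key] = gene_id
        builder.add_k27ac(te_iv, cfg.te_signal_median)
        own_k27_peaks[gene_id].append(builder.k27ac[-1])
        mid = te_iv.midpoint
        te_atac_iv = GenomicInterval(chrom, max(te_iv.start, mid - 150), min(te_iv.end, mid + 150))
        builder.add_atac(te_atac_iv, cfg.atac_signal_median)
        truth.planted_sites[key] = builder.add_gata2_sites(te_iv, cfg.gata_site_density_te)
        n_motifs = int(rng.poisson(cfg.motif_mean_te))
        motif_plan.append((gene_id, "TE", [te_atac_iv], n_motifs))

        # promoter peaks: H3K27ac (excluded by stitching) and ATAC (TSS profile)
        if rng.random() < cfg.promoter_peak_fraction:
            builder.add_k27ac(
                GenomicInterval(chrom, max(0, tss - 1_000), tss + 1_000),
                cfg.promoter_k27ac_signal_median,
            )
        builder.add_atac(
            GenomicInterval(chrom, max(0, tss - 150), tss + 150),
            cfg.promoter_atac_signal_median,
        )

    # H3K27ac distractors without H3K4me1: dropped by the potential-enhancer
    # filter, placed in silent-gene territory
    silent = [p for p in placements if not p[5]]
    for _ in range(cfg.n_distractor_k27ac):
        if not silent:
            break
        _, chrom, tss, _, _, _ = silent[int(rng.integers(0, len(silent)))]
        start = tss + int(rng.integers(15_000, 25_000))
        builder.add_k27ac(
            GenomicInterval(chrom, start, start + 800),
            cfg.te_signal_median,
            with_k4me1=False,
        )

    # --- genome sequence with planted motif words
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_arrays = {
        c: base_lookup[rng.integers(0, 4, size=cfg.chrom_sizes[c])]
        for c in chrom_names
    }

    _RC = str.maketrans("ACGT", "TGCA")

    def plant(iv: GenomicInterval, words: list[str]) -> int:
        """Write words into disjoint 12-bp slots of a region; returns #placed."""
        n_slots = max(len(iv) // 12, 1)
        order = rng.permutation(n_slots)
        placed = 0
        for w_i, word in enumerate(words[:n_slots]):
            slot = int(order[w_i])
            pos = iv.start + slot * 12
            if pos + len(word) > iv.end:
                continue
            if rng.random() < 0.5:
                word = word.translate(_RC)[::-1]
            seq_arrays[iv.chrom][pos : pos + len(word)] = np.frombuffer(
                word.encode(), dtype=np.uint8
            )
            placed += 1
        return placed

    # distribute each (gene, class) motif budget over that class's
    # accessible regions; the control (MITF-like) motif is drawn once per
    # row at a class-independent mean
    by_region: dict[tuple, list[str]] = {}
    region_rows: dict[tuple, tuple[str, str]] = {}
    for gene_id, cls, atac_ivs, n_gata in motif_plan:
        n_mitf = int(rng.poisson(cfg.mitf_motif_mean))
        for kind, n in (("gata", n_gata), ("mitf", n_mitf)):
            for _ in range(n):
                iv = atac_ivs[int(rng.integers(0, len(atac_ivs)))]
                key = (iv.chrom, iv.start, iv.end)
                region_rows[key] = (gene_id, cls)
                word = (
                    _GATA_WORDS[int(rng.integers(0, len(_GATA_WORDS)))]
                    if kind == "gata"
                    else _MITF_WORD
                )
                by_region.setdefault(key, []).append(word)
        truth.planted_motifs.setdefault(gene_id, {})[cls] = 0
    for (chrom, start, end), words in sorted(by_region.items()):
        placed = plant(GenomicInterval(chrom, start, end), words)
        gene_id, cls = region_rows[(chrom, start, end)]
        # clipping is rare (regions hold ~25 slots); attribute losses pro rata
        lost = len(words) - placed
        n_gata = sum(1 for w in words if w != _MITF_WORD)
        truth.planted_motifs[gene_id][cls] += max(n_gata - lost, 0)
    sequences = {c: arr.tobytes().decode("ascii") for c, arr in seq_arrays.items()}

    # --- expression coupled to own-enhancer regulatory potential
    induced_pool = list(expressed_ids)
    n_induced = int(round(cfg.induced_fraction * len(induced_pool)))
    induced_draw = set(rng.choice(induced_pool, size=n_induced, replace=False)) if n_induced else set()
    n_highly = int(round(cfg.highly_induced_subfraction * len(induced_draw)))
    highly = set(rng.choice(sorted(induced_draw), size=n_highly, replace=False)) if n_highly else set()

    genes: list[GeneModel] = []
    for gene_id, chrom, tss, strand, body, expressed in placements:
        if expressed:
            rp = regulatory_potential(tss, own_k27_peaks[gene_id], chrom=chrom)
            log_expr = cfg.expr_intercept + cfg.expr_slope * rp.score + rng.normal(0, cfg.expr_sigma)
            unstim = float(np.exp(log_expr))
            truth.expressed_genes.append(gene_id)
        else:
            unstim = float(_lognormal(rng, 1.0, 0.5))
        fold = 1.0
        if gene_id in induced_draw:
            fold = cfg.highly_induced_fold if gene_id in highly else cfg.induced_fold
        stim = unstim * fold
        truth.planted_induction_fold[gene_id] = fold
        if fold >= 2.0 and (unstim >= 30.0 or stim >= 30.0):
            truth.induced_genes.append(gene_id)
        body_iv = body
        if not (body_iv.start <= tss <= body_iv.end):  # clipped at chromosome edge
            body_iv = GenomicInterval(chrom, min(tss, body_iv.start), max(tss, body_iv.end), strand)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=body_iv,
                tss=tss,
                is_id_gene=gene_id in id_set,
                expression={"unstim": unstim, "stim": stim},
            )
        )
    truth.id_genes = sorted(id_set)

    return LandscapeBundle(
        config=cfg,
        genes=genes,
        k27ac=builder.k27ac,
        k4me1=builder.k4me1,
        atac=builder.atac,
        gata2=builder.gata2,
        sequences=sequences,
        truth=truth,
    )


def _scale_peaks(peaks, span_class: dict, factors: dict, rng, jitter_sigma: float,
                 as_reduction: bool):
    """Scale peak signals by enhancer-class factors with per-enhancer jitter."""
    spans = []
    for key, cls in span_class.items():
        loc, coords = key.split(":")
        start, end = coords.split("-")
        spans.append((loc, int(start), int(end), cls))
    # per-enhancer effective factor, jittered once per enhancer
    eff = []
    for loc, start, end, cls in spans:
        f = factors[cls]
        if jitter_sigma > 0:
            f = float(np.clip(rng.normal(f, jitter_sigma), 0.0, None))
            if as_reduction:
                f = float(np.clip(f, 0.0, 1.0))
        eff.append((loc, start, end, (1.0 - f) if as_reduction else f))
    out = []
    for pk in peaks:
        iv = pk.interval
        scale = None
        for loc, start, end, s in eff:
            if iv.chrom == loc and iv.start < end and start < iv.end:
                scale = s
                break
        if scale is None:
            out.append(pk)
        else:
            out.append(
                SignalPeak(iv, tuple(v * scale for v in pk.signal_by_replicate),
                           source_mark=pk.source_mark, name=pk.name)
            )
    return out


def apply_knockout(bundle: LandscapeBundle, reduction_map: Mapping | None = None,
                   seed: int = 0) -> LandscapeBundle:
    """Perturb a bundle as a GATA2 knockout.

    Accessibility, H3K4me1 and H3K27ac signal at every planted enhancer is
    scaled by ``1 - reduction`` for its class (with small per-enhancer
    jitter), and key-ID-gene mRNA is reduced by the configured fraction.
    """
    reductions = json.loads(json.dumps(reduction_map)) if reduction_map is not None \
        else bundle.truth.ko_reductions
    for mark, by_class in reductions.items():
        vals = [by_class] if mark == "mrna_key_id" else list(by_class.values())
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"knockout reduction {mark}={v} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([bundle.config.seed, 7_001, seed]))
    jit = bundle.config.ko_jitter_sigma
    cls_map = bundle.truth.enhancer_class

    atac = _scale_peaks(bundle.atac, cls_map, reductions["atac"], rng, jit, True)
    k4me1 = _scale_peaks(bundle.k4me1, cls_map, reductions["k4me1"], rng, jit, True)
    k27ac = _scale_peaks(bundle.k27ac, cls_map, reductions["k27ac"], rng, jit, True)

    key_id = set(bundle.truth.id_genes) & set(bundle.truth.se_genes)
    mrna_red = reductions["mrna_key_id"]
    genes = []
    for g in bundle.genes:
        if g.gene_id in key_id:
            f = float(np.clip(1.0 - (rng.normal(mrna_red, jit) if jit > 0 else mrna_red), 0.0, 1.0))
            expr = {"unstim": g.expression["unstim"] * f}
            expr["stim"] = expr["unstim"]  # knockout fails to upregulate
        else:
            expr = dict(g.expression)
        genes.append(GeneModel(g.gene_id, g.interval, g.tss, g.is_id_gene, expr))

    truth = replace(bundle.truth)
    truth.ko_reductions = reductions
    return LandscapeBundle(
        config=bundle.config, genes=genes, k27ac=k27ac, k4me1=k4me1, atac=atac,
        gata2=list(bundle.gata2), sequences=bundle.sequences, truth=truth,
        condition="knockout",
    )


def apply_activation(bundle: LandscapeBundle, folds: Mapping | None = None,
                     seed: int = 0) -> LandscapeBundle:
    """Perturb a bundle into the IgE-crosslinked (stimulated) state.

    H3K27ac and accessibility at the enhancers of planted induced genes are
    multiplied by their class folds; H3K4me1 is left untouched.
    """
    folds = json.loads(json.dumps(folds)) if folds is not None else bundle.truth.activation_folds
    rng = np.random.default_rng(np.random.SeedSequence([bundle.config.seed, 7_002, seed]))
    induced = set(bundle.truth.induced_genes)
    cls_map = {
        key: cls
        for key, cls in bundle.truth.enhancer_class.items()
        if bundle.truth.enhancer_gene.get(key) in induced
    }
    k27ac = _scale_peaks(bundle.k27ac, cls_map, folds["k27ac"], rng, 0.0, False)
    atac = _scale_peaks(bundle.atac, cls_map, folds["atac"], rng, 0.0, False)
    return LandscapeBundle(
        config=bundle.config, genes=list(bundle.genes), k27ac=k27ac,
        k4me1=list(bundle.k4me1), atac=atac, gata2=list(bundle.gata2),
        sequences=bundle.sequences, truth=bundle.truth, condition="stim",
    )
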