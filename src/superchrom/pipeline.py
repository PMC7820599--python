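"""End-to-end analyses: identity, activation, and knockout reports.

Each ``run_*`` function chains the stage modules (enhancer definition ->
stitching -> SE calling -> gene assignment -> occupancy / motif / enrichment
metrics) on in-memory inputs and returns a dict of tidy DataFrames plus a
JSON-serializable ``summary``.  With ``outdir`` set, one TSV per table and a
``summary.json`` (including every parameter value used) are written.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneModel, SignalPeak
from .enhancer_landscape import (
    StitchingParams,
    StitchedEnhancer,
    annotate_genomic_distribution,
    call_super_enhancers,
    define_potential_enhancers,
    se_counts_by_replicate,
    stitch,
)
from .gene_linking import (
    assign_enhancers,
    build_regulatory_domains,
    regulatory_potential_table,
)
from .occupancy_metrics import (
    gene_profiles,
    knockout_contrast,
    signal_at_enhancers,
)
from .motif_scan import PositionWeightMatrix, load_bundled_motif, motifs_per_gene
from .activation_analysis import (
    classify_induction,
    induced_regions,
    activation_induced_enhancers,
    label_key_genes,
    se_enrichment,
)

__all__ = [
    "call_enhancer_landscape",
    "mark_reads_by_gene_class",
    "run_identity_analysis",
    "run_activation_analysis",
    "run_knockout_analysis",
]


def _require(value, name: str, flag: str):
    if value is None:
        raise ValueError(f"missing input: {name} is required (flag {flag})")
    return value


def call_enhancer_landscape(
    k27ac: Sequence[SignalPeak],
    genes: Sequence[GeneModel],
    k4me1: Sequence[SignalPeak] | None = None,
    params: StitchingParams = StitchingParams(),
) -> list[StitchedEnhancer]:
    """Potential-enhancer definition (if H3K4me1 given), stitching, SE call."""
    peaks = define_potential_enhancers(k27ac, k4me1) if k4me1 is not None else list(k27ac)
    stitched = stitch(peaks, genes, params)
    return call_super_enhancers(stitched)


def enhancer_table(enhancers: Sequence[StitchedEnhancer]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "enhancer_id": e.enhancer_id,
                "total_signal": e.total_signal,
                "rank": e.rank,
                "class": e.enhancer_class,
                "n_constituents": len(e.constituent_peaks),
            }
            for e in enhancers
        ]
    )


def mark_reads_by_gene_class(
    assignments: Mapping[str, Sequence[StitchedEnhancer]],
    peaks: Sequence[SignalPeak],
) -> dict[tuple[str, str], float]:
    """Replicate-averaged, halved peak reads within each gene's SE/TE set.

    Quantifies an arbitrary mark (e.g. ATAC accessibility) inside assigned
    enhancer regions, keyed ``(gene_id, class)``.
    """
    all_enh: dict[str, StitchedEnhancer] = {}
    for enhs in assignments.values():
        for e in enhs:
            all_enh[e.enhancer_id] = e
    order = list(all_enh.values())
    signals = signal_at_enhancers(order, peaks)
    per_enh = {e.enhancer_id: float(np.mean(sig)) for e, sig in zip(order, signals)}
    out: dict[tuple[str, str], float] = {}
    for gene_id, enhs in assignments.items():
        for cls in ("SE", "TE"):
            subset = [e for e in enhs if e.enhancer_class == cls]
            if subset:
                out[(gene_id, cls)] = sum(per_enh[e.enhancer_id] for e in subset) / 2.0
    return out


def _class_means(values: Mapping[tuple[str, str], float]) -> dict[str, float]:
    by_cls: dict[str, list[float]] = {}
    for (_, cls), v in values.items():
        by_cls.setdefault(cls, []).append(v)
    return {cls: float(np.mean(v)) for cls, v in by_cls.items()}


def run_identity_analysis(
    genes: Sequence[GeneModel] | None = None,
    k27ac: Sequence[SignalPeak] | None = None,
    k4me1: Sequence[SignalPeak] | None = None,
    atac: Sequence[SignalPeak] | None = None,
    gata2: Sequence[SignalPeak] = (),
    sequences: Mapping[str, str] | None = None,
    condition: str = "unstim",
    params: StitchingParams = StitchingParams(),
    pwm: PositionWeightMatrix | None = None,
    min_expression: float = 30.0,
    expressed_floor: float = 5.0,
    chrom_sizes: Mapping[str, int] | None = None,
    outdir=None,
) -> dict:
    """The resting-state identity analysis.

    Calls SEs/TEs, annotates their genomic distribution, assigns them to
    expressed genes, computes occupancy profiles, regulatory potential and
    per-gene motif counts, and quantifies SE enrichment at identity genes.
    """
    genes = _require(genes, "gene models", "--genes")
    k27ac = _require(k27ac, "H3K27ac peaks", "--k27ac")
    k4me1 = _require(k4me1, "H3K4me1 peaks", "--k4me1")

    ranked = call_enhancer_landscape(k27ac, genes, k4me1, params)
    rep_counts = se_counts_by_replicate(ranked)
    categories, distribution = annotate_genomic_distribution(
        ranked, genes, promoter_window=params.tss_exclusion
    )
    domains = build_regulatory_domains(genes, chrom_sizes=chrom_sizes)
    assignments = assign_enhancers(ranked, domains, genes, condition, min_expression)
    profiles = gene_profiles(assignments, gata2)
    rp = regulatory_potential_table(genes, k27ac)

    motif_counts = pd.DataFrame(columns=["gene_id", "enhancer_class", "motif_count"])
    if sequences is not None and atac is not None:
        used_pwm = pwm or load_bundled_motif("GATA2")
        per_gene = motifs_per_gene(assignments, atac, sequences, used_pwm)
        motif_counts = pd.DataFrame(
            [
                {"gene_id": g, "enhancer_class": cls, "motif_count": n}
                for g, by_cls in per_gene.items()
                for cls, n in by_cls.items()
            ],
            columns=["gene_id", "enhancer_class", "motif_count"],
        )

    se_genes = {
        g for g, enhs in assignments.items() if any(e.is_super for e in enhs)
    }
    universe = [g.gene_id for g in genes if g.expression.get(condition, 0.0) > expressed_floor]
    id_genes = [g.gene_id for g in genes if g.is_id_gene and g.gene_id in set(universe)]
    non_id = [g for g in universe if g not in set(id_genes)]
    enrichment = None
    if id_genes and non_id:
        enrichment = se_enrichment(id_genes, non_id, se_genes)
    key_labels = label_key_genes(id_genes, universe, se_genes)

    summary: dict = {
        "parameters": {
            "stitch_distance": params.stitch_distance,
            "tss_exclusion": params.tss_exclusion,
            "min_expression": min_expression,
            "expressed_floor": expressed_floor,
            "condition": condition,
        },
        "n_stitched_enhancers": len(ranked),
        "n_super_enhancers": int(sum(e.is_super for e in ranked)),
        "n_typical_enhancers": int(sum(not e.is_super for e in ranked)),
        "mean_se_count_across_replicates": rep_counts["mean_se_count"],
        "mean_te_count_across_replicates": rep_counts["mean_te_count"],
        "genomic_distribution": distribution,
        "n_assigned_genes": len(assignments),
        "n_se_genes": len(se_genes),
        "n_key_id_genes": sum(1 for v in key_labels.values() if v == "key_ID"),
    }
    se_len = [e.length for e in ranked if e.is_super]
    te_len = [e.length for e in ranked if not e.is_super]
    if se_len and te_len:
        summary["se_te_length_ratio"] = float(np.mean(se_len) / np.mean(te_len))
    if enrichment is not None:
        summary["id_se_fraction"] = enrichment.fraction_a
        summary["non_id_se_fraction"] = enrichment.fraction_b
        summary["id_se_enrichment_fold"] = enrichment.fold
    for col, out_key in (
        ("sites_per_kb_per_enhancer", "site_density_ratio_se_te"),
        ("reads_per_kb_per_enhancer", "read_density_ratio_se_te"),
    ):
        cls_mean = profiles.groupby("enhancer_class")[col].mean()
        if {"SE", "TE"} <= set(cls_mean.index) and cls_mean["TE"] > 0:
            summary[out_key] = float(cls_mean["SE"] / cls_mean["TE"])
    if len(motif_counts):
        m = motif_counts.groupby("enhancer_class")["motif_count"].mean()
        if {"SE", "TE"} <= set(m.index) and m["TE"] > 0:
            summary["motif_count_ratio_se_te"] = float(m["SE"] / m["TE"])

    # expression of SE-carrying vs TE-only assigned genes (one-sided rank test)
    expr = {g.gene_id: g.expression.get(condition, 0.0) for g in genes}
    se_expr = [expr[g] for g in assignments if g in se_genes]
    te_expr = [expr[g] for g in assignments if g not in se_genes]
    if len(se_expr) >= 3 and len(te_expr) >= 3:
        u = stats.mannwhitneyu(se_expr, te_expr, alternative="greater")
        summary["se_gene_expression_median"] = float(np.median(se_expr))
        summary["te_gene_expression_median"] = float(np.median(te_expr))
        summary["se_vs_te_expression_p"] = float(u.pvalue)

    result = {
        "enhancers": enhancer_table(ranked).assign(genomic_category=categories),
        "ranked_enhancers": ranked,
        "assignments": assignments,
        "profiles": profiles,
        "regulatory_potential": rp,
        "motif_counts": motif_counts,
        "key_labels": key_labels,
        "summary": summary,
    }
    if outdir is not None:
        _write_report(result, outdir)
    return result


def run_activation_analysis(
    genes: Sequence[GeneModel] | None = None,
    k27ac_rest: Sequence[SignalPeak] | None = None,
    k4me1_rest: Sequence[SignalPeak] | None = None,
    atac_rest: Sequence[SignalPeak] | None = None,
    k27ac_stim: Sequence[SignalPeak] | None = None,
    atac_stim: Sequence[SignalPeak] | None = None,
    k4me1_stim: Sequence[SignalPeak] | None = None,
    params: StitchingParams = StitchingParams(),
    min_fpkm: float = 30.0,
    filter_mode: str = "both",
    min_fold: float = 1.5,
    min_reads: float = 10.0,
    expressed_floor: float = 5.0,
    outdir=None,
) -> dict:
    """Activation analysis: induction classes, induced enhancers, folds.

    Enhancers are called in the resting state; per-region reads in both
    states feed the declared fold-change rule for activation-increased
    regions, and the intersection of ATAC- and H3K27ac-increased regions
    yields the activation-induced enhancers.  Signal folds at SEs/TEs of
    induced genes and SE enrichment among induced genes are summarized.
    """
    genes = _require(genes, "gene models", "--genes")
    k27ac_rest = _require(k27ac_rest, "resting H3K27ac peaks", "--k27ac-rest")
    k4me1_rest = _require(k4me1_rest, "resting H3K4me1 peaks", "--k4me1-rest")
    k27ac_stim = _require(k27ac_stim, "stimulated H3K27ac peaks", "--k27ac-stim")

    expr_unstim = {g.gene_id: g.expression.get("unstim", 0.0) for g in genes}
    expr_stim = {g.gene_id: g.expression.get("stim", 0.0) for g in genes}
    induction = classify_induction(expr_unstim, expr_stim, min_fpkm, filter_mode)
    induced_genes = set(
        induction.loc[induction.label.isin(["induced", "highly_induced"]), "gene_id"]
    )

    ranked = call_enhancer_landscape(k27ac_rest, genes, k4me1_rest, params)
    domains = build_regulatory_domains(genes)
    assignments = assign_enhancers(ranked, domains, genes, "unstim", min_fpkm)

    def region_reads(peaks):
        return np.array(
            [np.asarray(s, dtype=float) for s in signal_at_enhancers(ranked, peaks)]
        )

    k27_un, k27_st = region_reads(k27ac_rest), region_reads(k27ac_stim)
    k27_increased, k27_mask = induced_regions(ranked, k27_un, k27_st, min_fold, min_reads)
    atac_increased, atac_mask, induced_enh = [], np.zeros(len(ranked), bool), []
    if atac_rest is not None and atac_stim is not None:
        at_un, at_st = region_reads(atac_rest), region_reads(atac_stim)
        atac_increased, atac_mask = induced_regions(ranked, at_un, at_st, min_fold, min_reads)
        induced_enh = activation_induced_enhancers(atac_increased, k27_increased)

    # signal folds at enhancers of induced genes, per class
    induced_enh_ids = {
        e.enhancer_id for g in induced_genes for e in assignments.get(g, [])
    }

    def fold_at(cls: str, un: np.ndarray, st: np.ndarray) -> float | None:
        idx = [
            i
            for i, e in enumerate(ranked)
            if e.enhancer_class == cls and e.enhancer_id in induced_enh_ids
        ]
        if not idx:
            return None
        tot_un, tot_st = un[idx].mean(axis=1).sum(), st[idx].mean(axis=1).sum()
        return float(tot_st / tot_un) if tot_un > 0 else None

    summary: dict = {
        "parameters": {
            "min_fpkm": min_fpkm,
            "filter_mode": filter_mode,
            "induced_region_min_fold": min_fold,
            "induced_region_min_reads": min_reads,
            "rule": "declared fold-change replacement for differential binding",
        },
        "induction_class_counts": induction.label.value_counts().to_dict(),
        "n_induced_genes": int(len(induced_genes)),
        "n_k27ac_increased_regions": int(k27_mask.sum()),
        "n_atac_increased_regions": int(atac_mask.sum()),
        "n_activation_induced_enhancers": len(induced_enh),
        "k27ac_fold_se_induced_genes": fold_at("SE", k27_un, k27_st),
        "k27ac_fold_te_induced_genes": fold_at("TE", k27_un, k27_st),
    }
    if atac_rest is not None and atac_stim is not None:
        summary["atac_fold_se_induced_genes"] = fold_at("SE", at_un, at_st)
    if k4me1_stim is not None:
        k4_un, k4_st = region_reads(k4me1_rest), region_reads(k4me1_stim)
        summary["k4me1_fold_se_induced_genes"] = fold_at("SE", k4_un, k4_st)
        summary["k4me1_fold_te_induced_genes"] = fold_at("TE", k4_un, k4_st)

    se_genes = {g for g, enhs in assignments.items() if any(e.is_super for e in enhs)}
    universe = [g.gene_id for g in genes if g.expression.get("unstim", 0.0) > expressed_floor
                or g.expression.get("stim", 0.0) > expressed_floor]
    other = [g for g in universe if g not in induced_genes]
    feature = [g for g in universe if g in induced_genes]
    if feature and other:
        enr = se_enrichment(feature, other, se_genes)
        summary["induced_se_fraction"] = enr.fraction_a
        summary["other_se_fraction"] = enr.fraction_b
        summary["induced_se_enrichment_fold"] = enr.fold
    key_labels = label_key_genes(
        feature, universe, se_genes,
        feature_label="activation_induced", nonfeature_label="not_induced",
    )

    result = {
        "induction": induction,
        "enhancers": enhancer_table(ranked),
        "ranked_enhancers": ranked,
        "k27ac_increased": k27_increased,
        "atac_increased": atac_increased,
        "activation_induced_enhancers": induced_enh,
        "key_labels": key_labels,
        "summary": summary,
    }
    if outdir is not None:
        _write_report(result, outdir)
    return result


def run_knockout_analysis(
    genes_wt: Sequence[GeneModel] | None = None,
    genes_ko: Sequence[GeneModel] | None = None,
    k27ac_wt: Sequence[SignalPeak] | None = None,
    k4me1_wt: Sequence[SignalPeak] | None = None,
    atac_wt: Sequence[SignalPeak] | None = None,
    k27ac_ko: Sequence[SignalPeak] | None = None,
    k4me1_ko: Sequence[SignalPeak] | None = None,
    atac_ko: Sequence[SignalPeak] | None = None,
    condition: str = "unstim",
    params: StitchingParams = StitchingParams(),
    min_expression: float = 30.0,
    wt_floor: float = 1.0,
    outdir=None,
) -> dict:
    """Knockout contrasts: per-gene-class percent reductions per mark.

    Enhancers and assignments come from the wild-type landscape; signal at
    the same regions is quantified in both genotypes and reduced to percent
    reductions with class medians and banding.
    """
    genes_wt = _require(genes_wt, "wild-type gene models", "--genes-wt")
    k27ac_wt = _require(k27ac_wt, "wild-type H3K27ac peaks", "--k27ac-wt")
    k4me1_wt = _require(k4me1_wt, "wild-type H3K4me1 peaks", "--k4me1-wt")

    ranked = call_enhancer_landscape(k27ac_wt, genes_wt, k4me1_wt, params)
    domains = build_regulatory_domains(genes_wt)
    assignments = assign_enhancers(ranked, domains, genes_wt, condition, min_expression)

    summary: dict = {
        "parameters": {"condition": condition, "wt_floor": wt_floor},
        "n_stitched_enhancers": len(ranked),
    }
    contrasts: dict[str, dict] = {}
    mark_pairs = {
        "atac": (atac_wt, atac_ko),
        "k27ac": (k27ac_wt, k27ac_ko),
        "k4me1": (k4me1_wt, k4me1_ko),
    }
    for mark, (wt_peaks, ko_peaks) in mark_pairs.items():
        if wt_peaks is None or ko_peaks is None:
            continue
        wt_vals = mark_reads_by_gene_class(assignments, wt_peaks)
        ko_vals = mark_reads_by_gene_class(assignments, ko_peaks)
        keyed_wt = {f"{g}|{c}": v for (g, c), v in wt_vals.items()}
        keyed_ko = {f"{g}|{c}": ko_vals.get((g, c), 0.0) for (g, c) in wt_vals}
        classes = {k: k.rsplit("|", 1)[1] for k in keyed_wt}
        contrast = knockout_contrast(keyed_wt, keyed_ko, classes, wt_floor)
        contrasts[mark] = contrast
        summary[f"{mark}_reduction_pct"] = {
            cls: d["median_reduction_pct"] for cls, d in contrast["by_class"].items()
        }

    if genes_ko is not None:
        se_genes = {g for g, enhs in assignments.items() if any(e.is_super for e in enhs)}
        key_id = [
            g.gene_id for g in genes_wt if g.is_id_gene and g.gene_id in se_genes
        ]
        expr_wt = {g.gene_id: g.expression.get(condition, 0.0) for g in genes_wt}
        expr_ko = {g.gene_id: g.expression.get(condition, 0.0) for g in genes_ko}
        if key_id:
            c = knockout_contrast(
                {g: expr_wt[g] for g in key_id},
                {g: expr_ko.get(g, 0.0) for g in key_id},
                wt_floor=wt_floor,
            )
            summary["key_id_mrna_reduction_pct"] = c["by_class"]["all"]["median_reduction_pct"]

    result = {
        "enhancers": enhancer_table(ranked),
        "ranked_enhancers": ranked,
        "assignments": assignments,
        "contrasts": contrasts,
        "summary": summary,
    }
    if outdir is not None:
        _write_report(result, outdir)
    return result


def _write_report(result: Mapping, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in result.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if "summary" in result:
        with open(out / "summary.json", "w") as fh:
            json.dump(result["summary"], fh, indent=1, sort_keys=True, default=str)
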