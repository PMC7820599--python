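"""Activation-response analysis: induction classes, activation-induced
enhancer detection, super-enhancer enrichment folds, and key-gene labels.

Induction classes follow fixed fold bands: *highly induced* means a
stimulated/unstimulated expression ratio above 10, *induced* from 2 to 10,
*unchanged* between 0.5 and 2, *repressed* below 0.5.  Genes expressed below
30 FPKM are filtered; by default the filter removes a gene only when it is
below 30 in BOTH conditions, so genes induced from a low baseline survive
(the strict either-condition reading is available via ``filter_mode``).

Differential-signal detection uses a declared fold-change rule (a region is
activation-increased when mean stimulated signal is at least 1.5-fold the
unstimulated mean and at least 10 RPM), replacing an external
differential-binding model; the thresholds are reported in output headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import intersect_any

__all__ = [
    "InductionClass",
    "EnrichmentResult",
    "classify_induction",
    "induced_regions",
    "activation_induced_enhancers",
    "se_enrichment",
    "label_key_genes",
    "INDUCTION_LABELS",
]

INDUCTION_LABELS = ("highly_induced", "induced", "unchanged", "repressed", "filtered")


@dataclass(frozen=True)
class InductionClass:
    gene_id: str
    fold: float  # stim / unstim, nan when filtered
    label: str


@dataclass(frozen=True)
class EnrichmentResult:
    fraction_a: float
    fraction_b: float
    fold: float
    p_hypergeom: float | None = None  # tail test; an extension beyond the fold


def _induction_label(fold: float) -> str:
    if fold > 10:
        return "highly_induced"
    if fold >= 2:
        return "induced"
    if fold >= 0.5:
        return "unchanged"
    return "repressed"


def classify_induction(
    expr_unstim: Mapping[str, float],
    expr_stim: Mapping[str, float],
    min_fpkm: float = 30.0,
    filter_mode: str = "both",
    fold_floor: float = 1.0,
) -> pd.DataFrame:
    """Classify each gene's activation response from its expression fold.

    ``filter_mode='both'`` filters genes below ``min_fpkm`` in both
    conditions; ``'either'`` filters genes below it in either condition.
    Folds are computed against ``max(unstim, fold_floor)`` so a silent
    baseline cannot produce an infinite ratio.
    """
    if filter_mode not in ("both", "either"):
        raise ValueError("filter_mode must be 'both' or 'either'")
    if set(expr_unstim) != set(expr_stim):
        raise ValueError("conditions cover different gene sets")
    rows = []
    for gene in expr_unstim:
        un, st = float(expr_unstim[gene]), float(expr_stim[gene])
        if un < 0 or st < 0:
            raise ValueError(f"gene {gene}: negative expression")
        low_un, low_st = un < min_fpkm, st < min_fpkm
        filtered = (low_un and low_st) if filter_mode == "both" else (low_un or low_st)
        if filtered:
            rows.append({"gene_id": gene, "unstim": un, "stim": st,
                         "fold": np.nan, "label": "filtered"})
            continue
        fold = st / max(un, fold_floor)
        rows.append({"gene_id": gene, "unstim": un, "stim": st,
                     "fold": fold, "label": _induction_label(fold)})
    return pd.DataFrame(rows, columns=["gene_id", "unstim", "stim", "fold", "label"])


def induced_regions(
    regions: Sequence,
    reads_unstim: np.ndarray,
    reads_stim: np.ndarray,
    min_fold: float = 1.5,
    min_reads: float = 10.0,
    fold_floor: float = 1.0,
) -> tuple[list, np.ndarray]:
    """Regions with activation-increased signal under the declared rule.

    ``reads_*`` are (n_regions, n_replicates) RPM matrices matched to
    ``regions``.  A region is increased when
    ``mean(stim) / max(mean(unstim), fold_floor) >= min_fold`` and
    ``mean(stim) >= min_reads``.  Returns the increased subset and the
    boolean mask.
    """
    un = np.atleast_2d(np.asarray(reads_unstim, dtype=float))
    st = np.atleast_2d(np.asarray(reads_stim, dtype=float))
    if un.shape[0] != len(regions) or st.shape[0] != len(regions):
        raise ValueError(
            f"region count {len(regions)} does not match read matrices "
            f"({un.shape[0]} unstim, {st.shape[0]} stim rows)"
        )
    mean_un, mean_st = un.mean(axis=1), st.mean(axis=1)
    fold = mean_st / np.maximum(mean_un, fold_floor)
    mask = (fold >= min_fold) & (mean_st >= min_reads)
    return [r for r, keep in zip(regions, mask) if keep], mask


def activation_induced_enhancers(atac_increased: Sequence, k27ac_increased: Iterable) -> list:
    """Regions increased in both accessibility and H3K27ac.

    Reported as the ATAC-increased records that overlap (>= 1 bp) any
    H3K27ac-increased region.
    """
    return intersect_any(atac_increased, k27ac_increased)


def se_enrichment(
    genes_with_feature: Iterable[str],
    background: Iterable[str],
    se_genes: Iterable[str],
    with_p: bool = True,
) -> EnrichmentResult:
    """Fold enrichment of SE association in a feature gene set vs background.

    ``fraction_a`` is the share of feature genes carrying a super-enhancer,
    ``fraction_b`` the share of background genes; ``fold = a / b``.  The
    hypergeometric tail p-value over the combined universe is an optional
    extra beyond the fold itself.
    """
    feature, bg, se = set(genes_with_feature), set(background), set(se_genes)
    if not bg:
        raise ValueError("empty background gene set")
    if not feature:
        raise ValueError("empty feature gene set")
    frac_a = len(feature & se) / len(feature)
    frac_b = len(bg & se) / len(bg)
    fold = frac_a / frac_b if frac_b > 0 else float("inf")
    p = None
    if with_p:
        universe = feature | bg
        k = len(feature & se)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(universe & se), len(feature))
        )
    return EnrichmentResult(fraction_a=frac_a, fraction_b=frac_b, fold=fold, p_hypergeom=p)


def label_key_genes(
    feature_genes: Iterable[str],
    universe: Iterable[str],
    se_genes: Iterable[str],
    feature_label: str = "ID",
    nonfeature_label: str = "non-ID",
) -> dict[str, str]:
    """Deterministic key-gene labels over a gene universe.

    A gene inside the feature set is ``key_<feature>`` iff it carries at
    least one super-enhancer, otherwise ``<feature>``; genes outside the
    feature set get ``nonfeature_label``.  For activation analyses use
    ``feature_label='activation_induced'`` and
    ``nonfeature_label='non-key_activation_induced'`` style labels.
    """
    feature, se = set(feature_genes), set(se_genes)
    labels = {}
    for gene in universe:
        if gene in feature:
            labels[gene] = f"key_{feature_label}" if gene in se else feature_label
        else:
            labels[gene] = nonfeature_label
    return labels
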