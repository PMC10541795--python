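"""Post-classification statistics.

Promoter variant burden (2-kb windows upstream of the TSS), magnitude of
expression divergence by transcript type, cross-tissue and
cross-generation fold-change concordance, and cell-type marker enrichment
of gene sets.  Marker sets and conservation-score tables are inputs here;
their computation (single-cell marker discovery, PhastCons/PhyloP, dN/dS)
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel, VariantRecord, write_bed
from .stats_core import hypergeom_upper_tail, pearson_corr, wilcoxon_rank_sum

PROMOTER_BP = 2000


@dataclass
class PromoterWindow:
    transcript_id: str
    chrom: str
    start: int  # 1-based closed
    end: int
    truncated: bool = False


def promoter_windows(
    transcripts: Sequence[TranscriptModel],
    width: int = PROMOTER_BP,
) -> list[PromoterWindow]:
    """Strand-aware 2-kb windows immediately upstream of each TSS.

    '+' transcript with TSS t -> [t-width, t-1]; '-' transcript ->
    [t+1, t+width].  The window abuts but never includes the TSS base.
    Windows running off the chromosome start are truncated and flagged.
    """
    out = []
    for tx in transcripts:
        t = tx.tss
        if tx.strand == "+":
            start, end = t - width, t - 1
        else:
            start, end = t + 1, t + width
        truncated = start < 1
        if truncated:
            start = 1
        if end < start:
            continue  # TSS at base 1 on '+': no upstream sequence at all
        out.append(PromoterWindow(tx.transcript_id, tx.chrom,
                                  start, end, truncated))
    return out


def write_promoter_bed(windows: Sequence[PromoterWindow], path) -> None:
    """BED (0-based half-open) export of the promoter windows."""
    write_bed(
        ((w.chrom, w.start, w.end, w.transcript_id) for w in windows), path)


def variant_burden(
    windows: Sequence[PromoterWindow],
    variants: Iterable[VariantRecord],
) -> pd.DataFrame:
    """SNV/indel counts and mean indel length per promoter window.

    A variant belongs to a window when its position falls inside the
    1-based closed interval.  Indel length = |len(alt) - len(ref)|; the
    mean is 0 when a window holds no indels.
    """
    variants = list(variants)
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    rows = []
    for w in windows:
        snv = 0
        indel_lengths = []
        for v in by_chrom.get(w.chrom, []):
            if w.start <= v.pos <= w.end:
                if v.kind == "snv":
                    snv += 1
                else:
                    indel_lengths.append(v.indel_length)
        rows.append({
            "transcript_id": w.transcript_id,
            "snv_count": snv,
            "indel_count": len(indel_lengths),
            "mean_indel_length": (float(np.mean(indel_lengths))
                                  if indel_lengths else 0.0),
        })
    return pd.DataFrame(rows).set_index("transcript_id")


BURDEN_STATS = ("snv_count", "indel_count", "mean_indel_length")


def compare_burden_by_category(
    burden: pd.DataFrame,
    categories: pd.Series,
    groups: Sequence[str] = ("cis", "trans", "conserved", "others"),
) -> pd.DataFrame:
    """Pairwise rank-sum p-values (plus medians) of promoter burden between
    regulatory categories.  Transcripts outside the named groups pool into
    ``others``; groups with fewer than two members are skipped with a
    warning row left out."""
    cats = categories.reindex(burden.index)
    named = [g for g in groups if g != "others"]
    pooled = cats.where(cats.isin(named), "others")
    rows = []
    for stat in BURDEN_STATS:
        for g1, g2 in combinations(groups, 2):
            x = burden.loc[pooled == g1, stat].dropna()
            y = burden.loc[pooled == g2, stat].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            rows.append({
                "statistic": stat, "group1": g1, "group2": g2,
                "median1": float(x.median()), "median2": float(y.median()),
                "p_value": wilcoxon_rank_sum(x, y),
                "n1": len(x), "n2": len(y),
            })
    return pd.DataFrame(rows)


def expression_divergence(
    log2fc: pd.Series,
    transcript_types: pd.Series,
    pcg_label: str = "PCG",
) -> dict:
    """|log2FC| comparison between PCGs and combined lncRNAs+TUCPs.

    Returns the two groups' absolute fold-changes, their medians, and the
    rank-sum p-value (nan when either group is smaller than 2).
    """
    types = transcript_types.reindex(log2fc.index)
    abs_fc = log2fc.abs()
    pcg = abs_fc[types == pcg_label].dropna()
    nc = abs_fc[types.isin(["lncRNA", "TUCP"])].dropna()
    p = (wilcoxon_rank_sum(pcg, nc)
         if len(pcg) >= 2 and len(nc) >= 2 else float("nan"))
    return {
        "pcg": pcg, "noncoding": nc,
        "median_pcg": float(pcg.median()) if len(pcg) else float("nan"),
        "median_noncoding": float(nc.median()) if len(nc) else float("nan"),
        "p_value": p,
    }


def cross_tissue_concordance(
    fold_changes: Mapping[str, pd.Series],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pearson r of log2 fold-changes between every pair of conditions.

    ``fold_changes`` maps a condition label (tissue, or an F0/F1 group
    within a tissue) to a per-transcript log2FC series restricted to the
    transcripts holding the relevant regulatory status there.  Pairs
    sharing fewer than ``min_shared`` transcripts are skipped.
    """
    rows = []
    labels = list(fold_changes)
    for l1, l2 in combinations(labels, 2):
        shared = fold_changes[l1].index.intersection(fold_changes[l2].index)
        if len(shared) < min_shared:
            continue
        x = fold_changes[l1].loc[shared]
        y = fold_changes[l2].loc[shared]
        rows.append({
            "pair": f"{l1}|{l2}",
            "n_pairs": len(shared),
            "pearson_r": pearson_corr(x, y),
        })
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    cell_type: str
    overlap: int
    expected: float
    enrichment_score: float
    p_value: float


def celltype_enrichment(
    gene_set: set[str],
    marker_sets: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Observed/expected enrichment of a gene set in cell-type markers.

    expected = |gene_set| * |markers| / |background|; score =
    observed/expected; p is the upper-tail hypergeometric probability.
    Gene and marker sets are intersected with the background first.
    """
    if not background:
        raise ValueError("empty background set")
    gene_set = gene_set & background
    out = []
    for cell_type, markers in marker_sets.items():
        markers = markers & background
        observed = len(gene_set & markers)
        expected = len(gene_set) * len(markers) / len(background)
        score = observed / expected if expected > 0 else 0.0
        p = hypergeom_upper_tail(observed, len(gene_set), len(markers),
                                 len(background))
        out.append(EnrichmentResult(cell_type, observed, expected, score, p))
    return out
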