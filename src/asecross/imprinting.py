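"""Imprinted-transcript detection from reciprocal-cross allele counts.

Allele counts are mapped to parental origin through each library's cross
direction (for an AxB library the sire is breed A, so the breed-A allele
is paternal), tested maternal vs paternal with the negative-binomial Wald
test, and Benjamini-Hochberg corrected across transcripts within the
tissue.  Adjusted p < 0.05 calls the transcript imprinted, with the parent
taken from the sign of the maternal/paternal log2 fold-change.  The
allelic ratio is the maternal fraction maternal/(maternal+paternal): 0
means fully paternal expression and 1 fully maternal.

Balancing libraries across both reciprocal directions is what cancels
breed (sequence-dependent) effects out of the parental comparison; a
tissue with a single direction is analysed with a warning, since there
parent of origin is confounded with breed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel
from .stats_core import bh_adjust, nb_diff_test_matrix

MATERNAL = "maternal"
PATERNAL = "paternal"
BIALLELIC = "biallelic"

#: detectability filter: total allele-informative counts required, and the
#: fraction of the tissue's libraries that must reach it
MIN_COUNT = 10
MIN_LIBRARY_FRACTION = 0.5

MAX_CLUSTER_GAP = 1_000_000  # bp


def parental_matrices(
    allele_a: pd.DataFrame,
    allele_b: pd.DataFrame,
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Reorder breed-allele counts into (maternal, paternal) matrices.

    Returns ``(maternal, paternal, single_direction_warning)``.  Columns
    follow the F1 libraries of ``design`` in order.
    """
    f1 = design[design["generation"] == "F1"]
    if f1["cross_direction"].isna().any():
        raise ValueError("every F1 library needs a cross_direction")
    bad = set(f1["cross_direction"]) - {"AxB", "BxA"}
    if bad:
        raise ValueError(f"unknown cross direction labels: {sorted(bad)}")
    libs = [l for l in f1["library_id"] if l in allele_a.columns]
    maternal = pd.DataFrame(index=allele_a.index, columns=libs, dtype=float)
    paternal = pd.DataFrame(index=allele_a.index, columns=libs, dtype=float)
    direction = dict(zip(f1["library_id"], f1["cross_direction"]))
    for lib in libs:
        if direction[lib] == "AxB":      # sire = breed A
            paternal[lib] = allele_a[lib]
            maternal[lib] = allele_b[lib]
        else:
            maternal[lib] = allele_a[lib]
            paternal[lib] = allele_b[lib]
    single = len({direction[l] for l in libs}) < 2
    if single:
        warnings.warn(
            "only one cross direction present: parent-of-origin is "
            "confounded with breed", stacklevel=2)
    return maternal, paternal, single


def allelic_ratio(maternal_total: float, paternal_total: float) -> float:
    """Maternal expression fraction; undefined (raises) when both are zero."""
    total = maternal_total + paternal_total
    if total <= 0:
        raise ValueError("allelic ratio undefined for zero total counts")
    return maternal_total / total


def call_imprinting(
    maternal: pd.DataFrame,
    paternal: pd.DataFrame,
    size_factors: np.ndarray | None = None,
    alpha: float = 0.05,
    min_count: int = MIN_COUNT,
) -> pd.DataFrame:
    """Per-transcript imprinting calls for one tissue.

    Transcripts first pass a detectability filter (total allele-informative
    counts >= ``min_count`` in at least half the libraries); the NB test
    compares maternal vs paternal columns and BH correction runs across the
    tested transcripts.  Returns a DataFrame indexed by transcript with
    log2_fold_change (maternal over paternal), p_value, padj,
    allelic_ratio, call, and a per-direction consistency diagnostic is left
    to the caller (the pooled parental test is the calling rule).
    """
    if not maternal.columns.equals(paternal.columns):
        raise ValueError("maternal/paternal matrices must be column-aligned")
    n_lib = maternal.shape[1]
    total = maternal.to_numpy(dtype=float) + paternal.to_numpy(dtype=float)
    detectable = (total >= min_count).sum(axis=1) >= np.ceil(
        MIN_LIBRARY_FRACTION * n_lib)
    tested = maternal.index[detectable]
    if len(tested) == 0:
        return pd.DataFrame(columns=["log2_fold_change", "p_value", "padj",
                                     "allelic_ratio", "call"])
    if size_factors is None:
        size_factors = np.ones(n_lib)
    res = nb_diff_test_matrix(
        maternal.loc[tested], paternal.loc[tested],
        size_factors, size_factors)
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    m_sum = (maternal.loc[tested] / size_factors).sum(axis=1)
    p_sum = (paternal.loc[tested] / size_factors).sum(axis=1)
    res["allelic_ratio"] = m_sum / (m_sum + p_sum)
    sig = res["padj"] < alpha
    res["call"] = np.where(
        sig & (res["log2_fold_change"] > 0), MATERNAL,
        np.where(sig & (res["log2_fold_change"] < 0), PATERNAL, BIALLELIC))
    res.index.name = "transcript_id"
    return res


def tissue_specificity(results: dict[str, pd.DataFrame]) -> pd.Series:
    """Number of tissues with an imprinting call, per union-set transcript.

    The union set holds every transcript imprinted in at least one tissue;
    transcripts imprinted nowhere are excluded.
    """
    counts: dict[str, int] = {}
    for tissue, res in results.items():
        imprinted = res.index[res["call"] != BIALLELIC]
        for tx in imprinted:
            counts[tx] = counts.get(tx, 0) + 1
    return pd.Series(counts, name="n_tissues", dtype=int).sort_index()


@dataclass
class ImprintCluster:
    chrom: str
    members: list[str]
    span: tuple[int, int]


def detect_clusters(
    positions: pd.DataFrame,
    max_gap: int = MAX_CLUSTER_GAP,
) -> tuple[list[ImprintCluster], dict]:
    """Chain imprinted transcripts within ``max_gap`` bp on each chromosome.

    ``positions`` needs columns transcript_id, chrom, pos (the transcript's
    representative position; the TSS is used throughout this package).
    Chains of two or more transcripts become clusters.  The summary reports
    how many transcripts sit in clusters and the clustered fraction.
    """
    clusters: list[ImprintCluster] = []
    for chrom, group in positions.groupby("chrom", sort=True):
        g = group.sort_values("pos")
        chain: list[tuple[str, int]] = []
        prev = None
        for row in g.itertuples(index=False):
            if prev is not None and row.pos - prev > max_gap:
                if len(chain) >= 2:
                    clusters.append(ImprintCluster(
                        chrom, [t for t, _ in chain],
                        (chain[0][1], chain[-1][1])))
                chain = []
            chain.append((row.transcript_id, int(row.pos)))
            prev = int(row.pos)
        if len(chain) >= 2:
            clusters.append(ImprintCluster(
                chrom, [t for t, _ in chain], (chain[0][1], chain[-1][1])))
    n_clustered = sum(len(c.members) for c in clusters)
    summary = {
        "n_clusters": len(clusters),
        "n_clustered": n_clustered,
        "fraction_clustered": (n_clustered / len(positions)
                               if len(positions) else float("nan")),
    }
    return clusters, summary


def cluster_positions(
    transcripts: dict[str, TranscriptModel],
    union_set,
) -> pd.DataFrame:
    """Representative (TSS) positions for the union-set transcripts."""
    rows = [
        {"transcript_id": tx, "chrom": transcripts[tx].chrom,
         "pos": transcripts[tx].tss}
        for tx in union_set if tx in transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "pos"])


def direction_consistency(
    maternal: pd.DataFrame,
    paternal: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Diagnostic: per-direction maternal allelic ratio for each transcript.

    Reported alongside the pooled test but not used for calling.
    """
    f1 = design[design["generation"] == "F1"]
    direction = dict(zip(f1["library_id"], f1["cross_direction"]))
    out = {}
    for d in ("AxB", "BxA"):
        libs = [l for l in maternal.columns if direction.get(l) == d]
        if not libs:
            continue
        m = maternal[libs].sum(axis=1)
        p = paternal[libs].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"ratio_{d}"] = m / (m + p)
    return pd.DataFrame(out)
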