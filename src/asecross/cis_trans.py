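"""Classification of breed expression divergence into regulatory categories.

Three tests feed the classification of each nonimprinted, expressed
transcript in a tissue:

* **P** — breed differential expression among F0 purebreds (NB Wald test,
  breed A vs breed B libraries);
* **F** — breed-allele differential expression within F1 hybrids (NB Wald
  test, breed-A allele vs breed-B allele counts, reciprocal directions
  pooled);
* **T** — Fisher's exact test on a 2x2 table of group-summed counts (rows
  F0/F1, columns breed A/breed B), asking whether the breed ratio differs
  between generations, i.e. whether a trans component exists.

Each family of p-values is Benjamini-Hochberg corrected independently
within the tissue, significance is taken at adjusted p < 0.05, and the
flag triple plus the two fold-change directions map onto seven categories:

=========  =====  =====  =====  =======================
category   sig_P  sig_F  sig_T  direction requirement
=========  =====  =====  =====  =======================
cis          1      1      0
trans        1      0      1
cis+trans    1      1      1    dir_P == dir_F (nonzero)
cis*trans    1      1      1    dir_P != dir_F
compensat.   0      1      1
conserved    0      0      0
ambiguous        everything else
=========  =====  =====  =====  =======================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import (TestResult, bh_adjust, estimate_size_factors,
                         fisher_exact, nb_diff_test, nb_diff_test_matrix)

CIS = "cis"
TRANS = "trans"
CIS_PLUS_TRANS = "cis_plus_trans"
CIS_TIMES_TRANS = "cis_times_trans"
COMPENSATORY = "compensatory"
CONSERVED = "conserved"
AMBIGUOUS = "ambiguous"
CATEGORIES = (CIS, TRANS, CIS_PLUS_TRANS, CIS_TIMES_TRANS,
              COMPENSATORY, CONSERVED, AMBIGUOUS)

ALPHA = 0.05


def classify(sig_p: bool, sig_f: bool, sig_t: bool,
             dir_p: int, dir_f: int) -> str:
    """Map the significance flags and ratio directions to one category.

    Total on the whole flag space; the (1,1,1) pattern with a zero
    direction is degenerate and lands in ``ambiguous``.
    """
    trio = (bool(sig_p), bool(sig_f), bool(sig_t))
    if trio == (True, True, False):
        return CIS
    if trio == (True, False, True):
        return TRANS
    if trio == (True, True, True):
        if dir_p == dir_f and dir_p != 0:
            return CIS_PLUS_TRANS
        if dir_p != dir_f:
            return CIS_TIMES_TRANS
        return AMBIGUOUS
    if trio == (False, True, True):
        return COMPENSATORY
    if trio == (False, False, False):
        return CONSERVED
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# the three tests
# ---------------------------------------------------------------------------

def test_P(f0_a, f0_b, size_factors_a=None, size_factors_b=None) -> TestResult:
    """Breed differential expression in F0 purebreds for one gene."""
    return nb_diff_test(f0_a, f0_b, size_factors_a, size_factors_b)


def test_F(f1_allele_a, f1_allele_b, size_factors=None) -> TestResult:
    """Breed-allele differential expression within F1 hybrids for one gene.

    Both alleles of a library share its size factor, so normalization
    cancels library depth out of the allelic comparison.
    """
    return nb_diff_test(f1_allele_a, f1_allele_b, size_factors, size_factors)


def test_T(ratio_table) -> float:
    """Fisher's exact p for a 2x2 generation x breed ratio table."""
    return fisher_exact(ratio_table)


def build_ratio_table(
    f0_a_norm: np.ndarray,
    f0_b_norm: np.ndarray,
    f1_a_norm: np.ndarray,
    f1_b_norm: np.ndarray,
    phi: float | tuple[float, float] = 0.0,
) -> np.ndarray:
    """2x2 table (rows F0/F1, columns breed A/B) of effective summed counts.

    Normalized counts are summed per group and each generation row is
    divided by its overdispersion factor 1 + phi * mu_h, where mu_h is the
    harmonic mean of the row's two per-library cell means, before rounding
    half-to-even.  The factor preserves the row ratios Fisher's test
    compares while matching the variance of the row's log ratio under
    negative-binomial replicate noise (delta method:
    Var(log R) = sum_g (1 + phi*mu_g) / (n*mu_g), and dividing both cells
    by 1 + phi*2*mu_a*mu_b/(mu_a+mu_b) equates the hypergeometric variance
    to it).  ``phi`` may be a single dispersion or an (F0, F1) pair; with
    phi = 0 the table reduces to plain normalized sums.  This function is
    the single substitution point for the ratio test's table construction.
    """
    if np.isscalar(phi):
        phi = (float(phi), float(phi))
    rows = []
    for (xa, xb), row_phi in zip(
            (((np.asarray(f0_a_norm, float)), np.asarray(f0_b_norm, float)),
             ((np.asarray(f1_a_norm, float)), np.asarray(f1_b_norm, float))),
            phi):
        mu_a, mu_b = xa.mean(), xb.mean()
        mu_h = (2 * mu_a * mu_b / (mu_a + mu_b)) if mu_a + mu_b > 0 else 0.0
        scale = 1.0 + max(row_phi, 0.0) * mu_h
        rows.append(np.round([xa.sum() / scale, xb.sum() / scale]))
    return np.asarray(rows, dtype=int)


# ---------------------------------------------------------------------------
# per-tissue pipeline
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    calls: pd.DataFrame      # per-transcript flags, directions, category
    tally: pd.DataFrame      # category counts (by transcript type if given)


def run_classification(
    f0_counts: pd.DataFrame,
    f1_allele_a: pd.DataFrame,
    f1_allele_b: pd.DataFrame,
    design: pd.DataFrame,
    transcripts=None,
    imprinted=None,
    transcript_types: pd.Series | None = None,
    alpha: float = ALPHA,
) -> ClassificationResult:
    """Classify every eligible transcript of one tissue.

    ``transcripts`` restricts the analysis to the expressed,
    allele-informative set; ``imprinted`` transcripts are rejected from the
    input (parent-of-origin effects must be removed before the breed-allele
    comparison).  F0 size factors come from median-of-ratios on the F0
    counts; F1 library size factors from the total (allele A + allele B)
    matrix.  BH correction runs independently per test family within the
    tissue.
    """
    f1_libs = list(f1_allele_a.columns)
    if list(f1_allele_b.columns) != f1_libs:
        raise ValueError("F1 allele matrices must share libraries")
    f0_design = design[design["generation"] == "F0"]
    a_libs = f0_design.loc[f0_design["breed"] == "A", "library_id"].tolist()
    b_libs = f0_design.loc[f0_design["breed"] == "B", "library_id"].tolist()
    if not a_libs or not b_libs:
        raise ValueError("both F0 breeds must be present in the design")
    missing = (set(a_libs) | set(b_libs)) - set(f0_counts.columns)
    if missing:
        raise ValueError(f"F0 libraries missing from counts: {sorted(missing)}")
    f1_design = design[design["generation"] == "F1"]
    if f1_design["cross_direction"].isna().any():
        raise ValueError("every F1 library needs a cross_direction")

    genes = f0_counts.index
    if transcripts is not None:
        genes = genes.intersection(pd.Index(transcripts))
    if imprinted is not None:
        imprinted = set(imprinted)
        offending = set(genes) & imprinted
        if offending:
            raise ValueError(
                f"imprinted transcripts in the classification input: "
                f"{sorted(offending)[:5]}{'...' if len(offending) > 5 else ''}")
    genes = genes.intersection(f1_allele_a.index)

    f0 = f0_counts.loc[genes]
    f1a = f1_allele_a.loc[genes]
    f1b = f1_allele_b.loc[genes]

    sf0 = estimate_size_factors(f0)
    sf0_a = sf0[[f0.columns.get_loc(l) for l in a_libs]]
    sf0_b = sf0[[f0.columns.get_loc(l) for l in b_libs]]
    sf1 = estimate_size_factors(f1a + f1b)

    res_p = nb_diff_test_matrix(f0[a_libs], f0[b_libs], sf0_a, sf0_b)
    res_f = nb_diff_test_matrix(f1a, f1b, sf1, sf1)

    ya = f0[a_libs].to_numpy(float) / sf0_a
    yb = f0[b_libs].to_numpy(float) / sf0_b
    fa = f1a.to_numpy(float) / sf1
    fb = f1b.to_numpy(float) / sf1
    # The larger of the two generations' dispersion estimates feeds the
    # ratio-table scaling: each estimate has few degrees of freedom, and an
    # underestimate would inflate the effective counts and over-reject.
    phi_t = np.maximum(res_p["phi"].to_numpy(), res_f["phi"].to_numpy())
    p_t = np.array([
        test_T(build_ratio_table(ya[i], yb[i], fa[i], fb[i], phi_t[i]))
        for i in range(len(genes))
    ])

    calls = pd.DataFrame(index=genes)
    calls["log2fc_P"] = res_p["log2_fold_change"]
    calls["log2fc_F"] = res_f["log2_fold_change"]
    calls["p_P"] = bh_adjust(res_p["p_value"].to_numpy())
    calls["p_F"] = bh_adjust(res_f["p_value"].to_numpy())
    calls["p_T"] = bh_adjust(p_t)
    calls["sig_P"] = calls["p_P"] < alpha
    calls["sig_F"] = calls["p_F"] < alpha
    calls["sig_T"] = calls["p_T"] < alpha
    calls["dir_P"] = np.sign(calls["log2fc_P"]).astype(int)
    calls["dir_F"] = np.sign(calls["log2fc_F"]).astype(int)
    calls["category"] = [
        classify(sp, sf_, st, dp, df_)
        for sp, sf_, st, dp, df_ in zip(
            calls["sig_P"], calls["sig_F"], calls["sig_T"],
            calls["dir_P"], calls["dir_F"])
    ]
    calls.index.name = "transcript_id"

    if transcript_types is not None:
        calls["transcript_type"] = transcript_types.reindex(genes)
        tally = (calls.groupby(["transcript_type", "category"], observed=True)
                 .size().unstack(fill_value=0)
                 .reindex(columns=list(CATEGORIES), fill_value=0))
    else:
        tally = (calls["category"].value_counts()
                 .reindex(list(CATEGORIES), fill_value=0).to_frame("n").T)
    return ClassificationResult(calls=calls, tally=tally)
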