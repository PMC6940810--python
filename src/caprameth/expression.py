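"""FPKM and two-group differential expression on RNA-seq counts.

Genes are called differentially expressed at BH-adjusted q <= 0.05 and
|log2 ratio| >= 1 (group 2 over group 1), mirroring the methylation
direction convention: DE-high means higher in the offspring group.

The test is a negative-binomial Wald test on library-size-normalised
counts: size factors by the median-of-ratios method, a method-of-moments
dispersion pooled across the two groups, and a delta-method standard error
for the log ratio of group means.  With two samples per group a per-gene
moment estimate of the dispersion is extremely noisy and regularly collapses
to zero, which would wildly inflate the Wald statistic; each gene's
dispersion is therefore moderated from below by the mean moment estimate
across all genes (a gene may exceed the genome-wide dispersion but not
undercut it), the same shrinkage direction the established NB DE tools
apply.  An external DE
table (gene, log2_ratio, p) can be supplied instead via
:func:`calls_from_table`, so results from any DE tool can drive the rest of
the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["gene_id", "base_mean_g1", "base_mean_g2", "log2_ratio",
              "p", "q", "call"]


def compute_fpkm(count, gene_length, library_size):
    """Fragments per kilobase of transcript per million fragments sequenced.

    count / ((gene_length / 1e3) * (library_size / 1e6)); vectorised.
    """
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(gene_length <= 0):
        raise ValueError("gene_length must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) / (gene_length / 1e3) / (library_size / 1e6)


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Falls back to relative library size when no gene is expressed in every
    sample.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(mat)
    ok = np.all(np.isfinite(log), axis=1)
    if ok.sum() == 0:
        lib = mat.sum(axis=0)
        return pd.Series(lib / np.exp(np.mean(np.log(lib))), index=counts.columns)
    ref = log[ok].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log[ok] - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def de_test(
    counts: pd.DataFrame,
    manifest,
    alpha_q: float = 0.05,
    min_abs_log2: float = 1.0,
    groups: tuple[str, str] = ("P0-GM", "F1-GM"),
) -> pd.DataFrame:
    """NB Wald differential expression between two groups of samples.

    ``counts``: integer matrix, genes x samples, gene ids as index.
    ``manifest``: mapping sample name -> group label.  Genes with zero
    counts in every sample are excluded from testing and reported NS with a
    missing p.  BH adjustment runs over all tested genes.
    """
    g1 = [s for s in counts.columns if manifest[s] == groups[0]]
    g2 = [s for s in counts.columns if manifest[s] == groups[1]]
    if not g1 or not g2:
        raise ValueError(f"both groups need >= 1 sample (got {len(g1)} and {len(g2)})")
    sf = size_factors(counts[g1 + g2])
    norm = counts[g1 + g2].div(sf, axis=1)
    n1, n2 = norm[g1].to_numpy(float), norm[g2].to_numpy(float)

    mu1, mu2 = n1.mean(axis=1), n2.mean(axis=1)
    log2_ratio = np.log2((mu2 + 1.0) / (mu1 + 1.0))

    # method-of-moments dispersion, pooled across the two groups
    def _alpha(x, mu):
        if x.shape[1] < 2:
            return np.zeros(x.shape[0])
        s2 = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / np.where(mu > 0, mu, 1.0) ** 2
        return np.where(mu > 0, a, 0.0)

    alpha_gene = (_alpha(n1, mu1) + _alpha(n2, mu2)) / 2.0
    expressed = (mu1 > 0) | (mu2 > 0)
    alpha_global = float(np.mean(alpha_gene[expressed])) if expressed.any() else 0.0
    alpha = np.maximum(alpha_gene, max(alpha_global, 1e-8))

    se = np.sqrt((1.0 / (mu1 + 1.0) + alpha) / len(g1)
                 + (1.0 / (mu2 + 1.0) + alpha) / len(g2))
    wald = np.log((mu2 + 1.0) / (mu1 + 1.0)) / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    tested = (counts[g1 + g2].to_numpy().sum(axis=1) > 0)
    p = np.where(tested, p, np.nan)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    call = np.where(~tested | np.isnan(q), "NS",
                    np.where((q <= alpha_q) & (log2_ratio >= min_abs_log2), "DE-high",
                             np.where((q <= alpha_q) & (log2_ratio <= -min_abs_log2),
                                      "DE-low", "NS")))
    out = pd.DataFrame({
        "gene_id": counts.index,
        "base_mean_g1": mu1, "base_mean_g2": mu2,
        "log2_ratio": np.where(tested, log2_ratio, 0.0),
        "p": p, "q": q, "call": call,
    }).reset_index(drop=True)
    return out


def add_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Per-sample FPKM matrix aligned to the count matrix."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    lib = counts.sum(axis=0)
    return pd.DataFrame(
        {s: compute_fpkm(counts[s], lengths.to_numpy(), lib[s]) for s in counts.columns},
        index=counts.index)


def calls_from_table(table: pd.DataFrame, alpha_q: float = 0.05,
                     min_abs_log2: float = 1.0) -> pd.DataFrame:
    """Apply the q/log2-ratio call rule to a precomputed (gene, log2_ratio, p) table."""
    out = table.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    out["call"] = np.where(
        (out["q"] <= alpha_q) & (out["log2_ratio"] >= min_abs_log2), "DE-high",
        np.where((out["q"] <= alpha_q) & (out["log2_ratio"] <= -min_abs_log2),
                 "DE-low", "NS"))
    return out
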