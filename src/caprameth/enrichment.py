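"""DMR-gene x DEG integration and hypergeometric term enrichment.

The integration table crosses the differentially methylated gene sets
(hyper / hypo, from DMR-to-gene assignment) with the differentially
expressed sets (DE-high / DE-low).  The two "repressive" cells —
hypermethylated & lowly expressed, hypomethylated & highly expressed — are
the canonical methylation-represses-expression pattern and are flagged.

Enrichment is a one-sided hypergeometric test per term: with a background
of N genes of which K belong to the term, drawing n genes and observing k
in the term, p = P(X >= k); BH adjustment across terms, significant at
q < 0.05.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from caprameth.expression import bh_adjust


@dataclasses.dataclass
class IntegrationTable:
    hyper_low: set
    hyper_high: set
    hypo_low: set
    hypo_high: set

    def venn_counts(self) -> dict[str, int]:
        return {
            "DM-high∩DE-low": len(self.hyper_low),
            "DM-high∩DE-high": len(self.hyper_high),
            "DM-low∩DE-low": len(self.hypo_low),
            "DM-low∩DE-high": len(self.hypo_high),
        }

    def repressive(self) -> dict[str, set]:
        """The canonical methylation-represses-expression cells."""
        return {"DM-high∩DE-low": self.hyper_low, "DM-low∩DE-high": self.hypo_high}


def integrate(dm_hyper: Iterable, dm_hypo: Iterable,
              de_high: Iterable, de_low: Iterable) -> IntegrationTable:
    """Exact set intersections of DM and DE gene sets."""
    dm_hyper, dm_hypo = set(dm_hyper), set(dm_hypo)
    de_high, de_low = set(de_high), set(de_low)
    return IntegrationTable(
        hyper_low=dm_hyper & de_low,
        hyper_high=dm_hyper & de_high,
        hypo_low=dm_hypo & de_low,
        hypo_high=dm_hypo & de_high,
    )


def enrich(gene_set: Iterable, background: Iterable,
           term_map: Mapping[str, Iterable], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in ``gene_set``.

    ``gene_set`` must be a subset of ``background``; genes outside the
    background are dropped with a warning.  Terms with no member in the
    background are skipped.  Returns term_id, overlap, set_size, term_size,
    background, p, q, significant (q < alpha).
    """
    background = set(background)
    gene_set = set(gene_set)
    stray = gene_set - background
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the background were dropped")
        gene_set &= background
    if not gene_set:
        warnings.warn("empty gene set: no enrichment computed")
        return pd.DataFrame(columns=["term_id", "overlap", "set_size", "term_size",
                                     "background", "p", "q", "significant"])
    N, n = len(background), len(gene_set)
    rows = []
    for term, members in term_map.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & gene_set)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "overlap", "set_size",
                                      "term_size", "background", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < alpha
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
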