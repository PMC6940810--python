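"""Stringent-criteria DMR calling between two groups of bisulfite samples.

A region is reported as differentially methylated when all of the following
hold, per sequence context (CG, CHG, CHH) independently:

- it is a maximal run of *eligible methylated sites* — sites with total
  depth > 10 and methylation-supporting depth > 4 (both strict) in at least
  one sample — in which adjacent sites are < 200 bp apart;
- its span (first to last site, 1-based inclusive) lies between 40 bp and
  10 kb;
- at least one sample has five or more eligible methylated sites inside it
  (``min_sites``, comparison configurable: the prevailing ``>=`` reading by
  default, the literal ``>`` reading via ``min_sites_mode="gt"``);
- the fold change of pooled methylation levels between the groups exceeds 2
  (symmetric: max/min, so 2-fold in either direction);
- the Pearson chi-square test (2x2 table of pooled methylated/unmethylated
  read counts x group, df=1, no continuity correction) gives p <= 0.05.

Samples within a group are pooled by summing read depths; there is no
replicate-variance model.  Direction is "hyper" when group 2 (offspring) is
more methylated than group 1 (parents), "hypo" otherwise.  P-values are
reported raw by default; an optional Benjamini-Hochberg flag adjusts them.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from caprameth.profiler import CONTEXTS

logger = logging.getLogger(__name__)

DMR_COLUMNS = ["dmr_id", "chrom", "start", "end", "context",
               "n_sites_g1", "n_sites_g2", "level_g1", "level_g2",
               "fold_change", "chi2", "p", "direction"]


@dataclasses.dataclass
class DMRParams:
    """Thresholds of the stringent criteria (defaults as published)."""

    min_total_depth: int = 10       # site eligible iff total depth > this
    min_meth_depth: int = 4         # ... and methylated depth > this
    max_gap: int = 200              # adjacent eligible sites < this apart
    min_len: int = 40               # region span bounds, bp (inclusive)
    max_len: int = 10_000
    min_sites: int = 5              # eligible methylated sites in >=1 sample
    min_sites_mode: str = "ge"      # "ge" (>= min_sites) or "gt" (> min_sites)
    min_fold_change: float = 2.0    # strict >
    alpha: float = 0.05             # p <= alpha
    pseudocount: float = 0.5        # added to all 4 pooled cells iff any is 0
    bh_correct: bool = False        # optional FDR adjustment of region p-values

    def __post_init__(self):
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.min_sites_mode not in ("ge", "gt"):
            raise ValueError("min_sites_mode must be 'ge' or 'gt'")


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square statistic of the 2x2 table [[a, b], [c, d]].

    Closed form n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); df = 1, no
    continuity correction.  Zero marginals give 0 (no evidence).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def eligible_sites(calls: pd.DataFrame, min_total_depth: int = 10,
                   min_meth_depth: int = 4) -> pd.DataFrame:
    """Sites with total depth > min_total_depth and meth depth > min_meth_depth."""
    return calls[(calls["total_depth"] > min_total_depth)
                 & (calls["meth_depth"] > min_meth_depth)]


def build_candidate_regions(
    eligible: Mapping[str, pd.DataFrame],
    max_gap: int = 200,
    min_len: int = 40,
    max_len: int = 10_000,
    min_sites: int = 5,
    min_sites_mode: str = "ge",
) -> pd.DataFrame:
    """Chain eligible methylated sites (union over samples) into candidates.

    Per (chrom, context): maximal runs of union positions with successive
    gaps < ``max_gap``; a run survives iff its span lies in
    [min_len, max_len] and at least one sample contributes ``min_sites``
    eligible sites inside it.  Returns chrom, start, end, context,
    n_sites_union, max_sample_sites.
    """
    sample_pos: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    union: dict[tuple[str, str], set] = {}
    for name, df in eligible.items():
        sample_pos[name] = {}
        for (chrom, ctx), sub in df.groupby(["chrom", "context"], observed=True):
            pos = np.unique(sub["pos"].to_numpy())
            sample_pos[name][(chrom, ctx)] = pos
            union.setdefault((chrom, ctx), set()).update(pos.tolist())

    rows = []
    need = min_sites if min_sites_mode == "ge" else min_sites + 1
    for (chrom, ctx), posset in sorted(union.items()):
        pos = np.array(sorted(posset))
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            first, last = int(pos[s]), int(pos[e])
            span = last - first + 1
            if not min_len <= span <= max_len:
                continue
            best = 0
            for name in sample_pos:
                p = sample_pos[name].get((chrom, ctx))
                if p is None:
                    continue
                cnt = int(np.searchsorted(p, last, side="right")
                          - np.searchsorted(p, first, side="left"))
                best = max(best, cnt)
            if best >= need:
                rows.append((chrom, first, last, ctx, int(e - s + 1), best))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "n_sites_union", "max_sample_sites"])


class _PooledIndex:
    """Sorted position index with depth prefix sums, for fast region pooling."""

    def __init__(self, calls_list: Sequence[pd.DataFrame]):
        pooled = pd.concat(calls_list, ignore_index=True) if calls_list else \
            pd.DataFrame(columns=["chrom", "pos", "context", "meth_depth", "total_depth"])
        pooled = pooled[pooled["total_depth"] > 0]
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (chrom, ctx), sub in pooled.groupby(["chrom", "context"], observed=True):
            g = sub.groupby("pos", observed=True)[["meth_depth", "total_depth"]].sum()
            pos = g.index.to_numpy()
            self._idx[(chrom, ctx)] = (
                pos,
                np.concatenate([[0], np.cumsum(g["meth_depth"].to_numpy())]),
                np.concatenate([[0], np.cumsum(g["total_depth"].to_numpy())]),
            )

    def query(self, chrom: str, ctx: str, start: int, end: int) -> tuple[int, int, int]:
        """(n_sites, meth, total) pooled over covered sites in [start, end]."""
        entry = self._idx.get((chrom, ctx))
        if entry is None:
            return 0, 0, 0
        pos, cm, ct = entry
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="right")
        return int(j - i), int(cm[j] - cm[i]), int(ct[j] - ct[i])


def test_region(
    region: tuple[str, int, int, str],
    group1_index: _PooledIndex,
    group2_index: _PooledIndex,
    pseudocount: float = 0.5,
    min_fold_change: float = 2.0,
    alpha: float = 0.05,
) -> dict | None:
    """Chi-square + fold-change test of one candidate region.

    Returns a record dict (tested region, regardless of significance — the
    ``called`` flag marks whether it meets fold change > 2 and p <= alpha),
    or None when either group has no covered site in the region.
    """
    chrom, start, end, ctx = region
    n1, m1, t1 = group1_index.query(chrom, ctx, start, end)
    n2, m2, t2 = group2_index.query(chrom, ctx, start, end)
    if t1 == 0 or t2 == 0:
        logger.info("region %s:%d-%d (%s) skipped: a group has zero depth",
                    chrom, start, end, ctx)
        return None
    u1, u2 = t1 - m1, t2 - m2
    cells = [m1, u1, m2, u2]
    if min(cells) == 0:
        cells = [c + pseudocount for c in cells]
    pm1, pu1, pm2, pu2 = cells
    level1, level2 = m1 / t1, m2 / t2
    l1, l2 = pm1 / (pm1 + pu1), pm2 / (pm2 + pu2)
    fold = max(l1, l2) / min(l1, l2)
    chi2 = pearson_chi2_2x2(pm1, pu1, pm2, pu2)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    direction = "hyper" if level2 > level1 else "hypo"
    return dict(chrom=chrom, start=start, end=end, context=ctx,
                n_sites_g1=n1, n_sites_g2=n2, level_g1=level1, level_g2=level2,
                fold_change=fold, chi2=chi2, p=p, direction=direction,
                called=(fold > min_fold_change and p <= alpha))


def call_dmrs(
    samples: Mapping[str, pd.DataFrame],
    manifest: Mapping[str, str],
    params: DMRParams | None = None,
    groups: tuple[str, str] = ("P0-GM", "F1-GM"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full DMR calling: eligibility -> chaining -> per-region test, per context.

    ``manifest`` maps sample name to group label; ``groups`` fixes which
    label is group 1 (reference) and group 2 (direction anchor).  Returns
    (dmrs, summary, tested): called DMR records, hyper/hypo counts per
    context, and the full table of tested candidates including
    non-significant ones (with a ``called`` flag).
    """
    params = params or DMRParams()
    g1_names = [s for s, g in manifest.items() if g == groups[0]]
    g2_names = [s for s, g in manifest.items() if g == groups[1]]
    if not g1_names or not g2_names:
        raise ValueError(f"both groups need >= 1 sample; manifest groups: "
                         f"{sorted(set(manifest.values()))}, wanted {groups}")
    unknown = set(manifest.values()) - set(groups)
    if unknown:
        raise ValueError(f"manifest contains unknown groups: {sorted(unknown)}")

    elig = {name: eligible_sites(df, params.min_total_depth, params.min_meth_depth)
            for name, df in samples.items()}
    candidates = build_candidate_regions(
        elig, params.max_gap, params.min_len, params.max_len,
        params.min_sites, params.min_sites_mode)

    idx1 = _PooledIndex([samples[s] for s in g1_names])
    idx2 = _PooledIndex([samples[s] for s in g2_names])
    records = []
    for cand in candidates.itertuples(index=False):
        rec = test_region((cand.chrom, cand.start, cand.end, cand.context),
                          idx1, idx2, params.pseudocount,
                          params.min_fold_change, params.alpha)
        if rec is not None:
            records.append(rec)
    tested = pd.DataFrame(records, columns=DMR_COLUMNS[1:] + ["called"]) \
        if records else pd.DataFrame(columns=DMR_COLUMNS[1:] + ["called"])

    if params.bh_correct and len(tested):
        from caprameth.expression import bh_adjust

        tested = tested.assign(q=bh_adjust(tested["p"].to_numpy()))
        tested["called"] = (tested["fold_change"] > params.min_fold_change) \
            & (tested["q"] <= params.alpha)

    dmrs = tested[tested["called"]].drop(columns=["called"]).reset_index(drop=True)
    dmrs.insert(0, "dmr_id", [f"DMR{i + 1:05d}" for i in range(len(dmrs))])

    rows = []
    for ctx in CONTEXTS:
        sub = dmrs[dmrs["context"] == ctx]
        rows.append((ctx, int((sub["direction"] == "hyper").sum()),
                     int((sub["direction"] == "hypo").sum())))
    summary = pd.DataFrame(rows, columns=["context", "n_hyper", "n_hypo"])
    return dmrs, summary, tested


def length_distribution(dmrs: pd.DataFrame, bins: Sequence[int] | None = None) -> pd.DataFrame:
    """Hyper/hypo DMR length histogram (span = end - start + 1)."""
    if bins is None:
        bins = [40, 100, 200, 500, 1000, 2000, 5000, 10_001]
    lengths = dmrs["end"] - dmrs["start"] + 1
    rows = []
    for direction in ("hyper", "hypo"):
        lens = lengths[dmrs["direction"] == direction]
        hist, edges = np.histogram(lens, bins=bins)
        for k, h in zip(range(len(hist)), hist):
            rows.append((direction, int(edges[k]), int(edges[k + 1]), int(h)))
    return pd.DataFrame(rows, columns=["direction", "len_min", "len_max", "count"])
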