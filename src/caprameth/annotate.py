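"""DMR-to-gene assignment and genomic feature distribution.

A DMR is assigned to a gene (or TE) when it overlaps, by at least 1 bp, the
feature body or either 2-kb flank.  The reported relation is strand-aware:
``upstream2k`` is the promoter side (2 kb 5' of the TSS), ``downstream2k``
the 2 kb past the 3' end.  A gene is called hypermethylated when any
assigned DMR is hyper (likewise hypo); a gene can carry both labels.

For the genome-wide distribution each DMR gets exactly one primary feature
by its midpoint, with precedence promoter2k > exon > intron > downstream2k
> intergenic; CpG-island overlap is reported as an independent boolean.
All coordinates in the public frames are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
from intervaltree import IntervalTree

FEATURE_ORDER = ["promoter2k", "exon", "intron", "downstream2k", "intergenic"]


@dataclasses.dataclass
class GeneModel:
    """Gene with strand-aware derived flanks; TEs use the same interface."""

    gene_id: str
    chrom: str
    start: int          # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def promoter(self, flank: int = 2000) -> tuple[int, int]:
        """2 kb upstream of the TSS, clipped at 1."""
        if self.strand == "-":
            return (self.end + 1, self.end + flank)
        return (max(1, self.start - flank), self.start - 1)

    def downstream(self, flank: int = 2000) -> tuple[int, int]:
        if self.strand == "-":
            return (max(1, self.start - flank), self.start - 1)
        return (self.end + 1, self.end + flank)


def _genes_from_frame(genes: pd.DataFrame) -> list[GeneModel]:
    return [GeneModel(g.gene_id, g.chrom, int(g.start), int(g.end), g.strand,
                      [tuple(map(int, e)) for e in (g.exons or [])])
            for g in genes.itertuples(index=False)]


def _check_chrom_overlap(dmrs: pd.DataFrame, features: pd.DataFrame, what: str) -> None:
    if len(dmrs) == 0 or len(features) == 0:
        return
    dchroms, fchroms = set(dmrs["chrom"]), set(features["chrom"])
    if not dchroms & fchroms:
        raise ValueError(
            f"no shared chromosomes between DMRs and {what}: "
            f"DMRs use {sorted(dchroms)}, {what} use {sorted(fchroms)}")


def map_dmrs_to_genes(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    tes: pd.DataFrame | None = None,
    flank: int = 2000,
) -> tuple[pd.DataFrame, dict[str, set], pd.DataFrame]:
    """Assign DMRs to genes (and TEs) overlapping body or either 2-kb flank.

    Returns (assignments, dm_gene_sets, te_assignments):
    assignments has one row per (gene, DMR) pair with a relation in
    {upstream2k, body, downstream2k} (body wins when the DMR touches both a
    flank and the body); dm_gene_sets maps "hyper"/"hypo" to gene-id sets.
    """
    _check_chrom_overlap(dmrs, genes, "genes")
    models = _genes_from_frame(genes)
    trees: dict[str, IntervalTree] = {}
    for gm in models:
        # index the padded span; half-open tree coordinates
        trees.setdefault(gm.chrom, IntervalTree()).addi(
            max(0, gm.start - flank), gm.end + flank + 1, gm)

    rows = []
    dm_sets: dict[str, set] = {"hyper": set(), "hypo": set()}
    for d in dmrs.itertuples(index=False):
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(d.start, d.end + 1),
                          key=lambda h: h.data.gene_id):
            gm: GeneModel = hit.data
            if d.start <= gm.end and d.end >= gm.start:
                relation = "body"
            else:
                ps, pe = gm.promoter(flank)
                relation = "upstream2k" if (d.start <= pe and d.end >= ps) \
                    else "downstream2k"
            rows.append((gm.gene_id, d.dmr_id, relation, d.direction, d.context))
            if d.direction in dm_sets:
                dm_sets[d.direction].add(gm.gene_id)
    assignments = pd.DataFrame(
        rows, columns=["gene_id", "dmr_id", "relation", "direction", "context"])

    te_rows = []
    if tes is not None and len(tes):
        _check_chrom_overlap(dmrs, tes, "TEs")
        ttrees: dict[str, IntervalTree] = {}
        for t in tes.itertuples(index=False):
            ttrees.setdefault(t.chrom, IntervalTree()).addi(
                max(0, int(t.start) - flank), int(t.end) + flank + 1, t)
        for d in dmrs.itertuples(index=False):
            tree = ttrees.get(d.chrom)
            if tree is None:
                continue
            for hit in sorted(tree.overlap(d.start, d.end + 1),
                              key=lambda h: h.data.te_id):
                t = hit.data
                relation = "body" if (d.start <= t.end and d.end >= t.start) else "flank2k"
                te_rows.append((t.te_id, d.dmr_id, relation, d.direction, d.context))
    te_assignments = pd.DataFrame(
        te_rows, columns=["te_id", "dmr_id", "relation", "direction", "context"])
    return assignments, dm_sets, te_assignments


def feature_distribution(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    cgis: pd.DataFrame | None = None,
    flank: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary-feature counts per context using the DMR midpoint.

    Precedence promoter2k > exon > intron > downstream2k > intergenic; the
    categories partition the DMR set, so counts sum to the number of DMRs.
    Returns (per_dmr, counts): per-DMR primary feature + independent
    ``in_cgi`` flag, and the context x feature count table.
    """
    models = _genes_from_frame(genes)
    cgi_trees: dict[str, IntervalTree] = {}
    if cgis is not None:
        for c in cgis.itertuples(index=False):
            # CGI frames from the simulator are 0-based half-open
            cgi_trees.setdefault(c.chrom, IntervalTree()).addi(
                int(c.start) + 1, int(c.end) + 1)

    feats: dict[str, IntervalTree] = {}

    def add(chrom, s, e, kind):
        if e >= s:
            feats.setdefault(chrom, IntervalTree()).addi(s, e + 1, kind)

    for gm in models:
        ps, pe = gm.promoter(flank)
        ds, de = gm.downstream(flank)
        add(gm.chrom, ps, pe, "promoter2k")
        add(gm.chrom, ds, de, "downstream2k")
        exons = gm.exons or [(gm.start, gm.end)]
        for es, ee in exons:
            add(gm.chrom, es, ee, "exon")
        add(gm.chrom, gm.start, gm.end, "intron_body")  # resolved below

    rows = []
    for d in dmrs.itertuples(index=False):
        mid = (d.start + d.end) // 2
        kinds = {h.data for h in feats.get(d.chrom, IntervalTree()).overlap(mid, mid + 1)}
        if "intron_body" in kinds and "exon" not in kinds:
            kinds.add("intron")
        kinds.discard("intron_body")
        primary = next((k for k in FEATURE_ORDER if k in kinds), "intergenic")
        in_cgi = bool(cgi_trees.get(d.chrom, IntervalTree()).overlap(d.start, d.end + 1))
        rows.append((d.dmr_id, d.context, d.direction, primary, in_cgi))
    per_dmr = pd.DataFrame(rows, columns=["dmr_id", "context", "direction",
                                          "feature", "in_cgi"])
    counts = (per_dmr.groupby(["context", "feature"], observed=True)
              .size().rename("count").reset_index())
    return per_dmr, counts
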