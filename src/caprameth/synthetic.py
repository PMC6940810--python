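"""Planted-truth simulator for the whole pipeline.

Generates a small mammalian-style genome, gene/TE annotation with a
synthetic term vocabulary, per-sample bisulfite call tables with planted
differentially methylated regions (DMRs), an RNA-seq count matrix with
planted differentially expressed genes (a subset causally linked to
promoter DMRs of the opposite sign), and raw reads with known QC labels.
Every generator is deterministic per seed and writes truth tables so
downstream callers can be scored against known answers.

Methylome landscape
-------------------
Mammalian CG methylation is modelled as alternating highly methylated "sea"
domains (2-8 kb) and short unmethylated valleys (400-900 bp, level ~0.01),
mimicking the methylated genome punctuated by CpG-island-like hypomethylated
troughs.  Valleys are wide and unmethylated enough that runs of methylated
sites terminate there, so each domain is a separately testable region.  ``cg_level`` is the *genome-wide mean* CG level; the sea-domain
level is solved from the realised valley site fraction so the pooled
genome-wide estimate equals ``cg_level`` by construction.  CHG and CHH sites
sit at their (low) baselines everywhere.  A planted DMR occupies one whole
sea domain (resized to ``dmr_length``), so the run of methylated sites the
DMR caller chains coincides with the truth interval.  Inside a planted DMR
the lower group sits at ``dmr_low_level`` and the higher group at
``dmr_low_level + dmr_delta`` (direction decides which group is which), so
the true-level fold change exceeds 2 whenever
``(dmr_low_level + dmr_delta) / dmr_low_level > 2``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from caprameth.profiler import classify_all_cytosines

VALLEY_LEVEL = 0.01  # CpG-island-like troughs are essentially unmethylated
BETA_CONCENTRATION = 80.0  # site-to-site wobble of true levels around their mean

TERM_VOCABULARY = [
    ("T{:04d}".format(i + 1), desc)
    for i, desc in enumerate([
        "keratinocyte differentiation", "hair follicle morphogenesis",
        "Wnt signaling", "BMP signaling", "cell cycle", "apoptosis",
        "chromatin remodeling", "DNA methylation maintenance",
        "lipid metabolism", "collagen biosynthesis", "immune response",
        "angiogenesis", "cytoskeleton organization", "RNA processing",
        "protein transport", "ion homeostasis", "oxidative stress response",
        "stem cell maintenance", "extracellular matrix", "melanogenesis",
    ])
]


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    dmr_truth: pd.DataFrame       # dmr_id chrom start end context direction delta
    de_truth: pd.DataFrame        # gene_id true_log2fc
    linked_genes: pd.DataFrame    # gene_id dmr_id link_sign
    seed: int


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    n_chrom: int = 1,
    chrom_length: int = 100_000,
    gc_fraction: float = 0.42,
    cgi_density: float = 10.0,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with CpG-island-like GC-rich intervals.

    Returns (chrom -> uppercase sequence, CGI table with columns
    chrom/start/end, 0-based half-open).  ``cgi_density`` is islands per Mb.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    p_bg = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                     gc_fraction / 2, (1 - gc_fraction) / 2])
    cgi_gc = 0.65
    p_cgi = np.array([(1 - cgi_gc) / 2, cgi_gc / 2, cgi_gc / 2, (1 - cgi_gc) / 2])

    genome: dict[str, str] = {}
    cgi_rows = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        seq = rng.choice(bases, size=chrom_length, p=p_bg)
        n_cgi = int(round(cgi_density * chrom_length / 1e6))
        starts = np.sort(rng.integers(0, max(chrom_length - 1200, 1), size=n_cgi))
        for s in starts:
            length = int(rng.integers(400, 1001))
            e = min(s + length, chrom_length)
            seq[s:e] = rng.choice(bases, size=e - s, p=p_cgi)
            cgi_rows.append((chrom, int(s), int(e)))
        genome[chrom] = seq.tobytes().decode("ascii")
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    return genome, cgis


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    genome: Mapping[str, str],
    n_genes: int = 40,
    n_tes: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Non-overlapping gene models with exons, TE intervals, and a term map.

    Genes keep >= 2 kb clearance from chromosome ends and from each other so
    promoter/downstream flanks never run off the sequence.  Coordinates in
    the returned frames are 1-based inclusive (GFF3 convention); ``exons``
    holds a list of (start, end) pairs in the same convention.

    Returns (genes, tes, term_map) where term_map maps term_id -> gene ids.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    placements = []
    per_chrom = {c: [] for c in chroms}
    # round-robin placement with >= 2 kb clearance plus room between genes
    remaining = n_genes
    for c in chroms:
        L = len(genome[c])
        cursor = 2000 + int(rng.integers(0, 1000))
        while remaining > 0:
            glen = int(rng.integers(1000, 4001))
            if cursor + glen + 2000 > L:
                break
            per_chrom[c].append((cursor, cursor + glen))
            placements.append((c, cursor, cursor + glen))
            cursor += glen + 4200 + int(rng.integers(0, 3000))
            remaining -= 1
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError(
            f"genome too small for {n_genes} genes with 2 kb clearance; "
            f"placed only {n_genes - remaining}")

    gene_rows = []
    for gi, (chrom, s0, e0) in enumerate(placements):
        gene_id = f"gene{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        glen = e0 - s0
        n_ex = int(rng.integers(1, 5))
        # carve exons by splitting the body at sorted cut points
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False)) \
            if n_ex > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [glen]])
        exons = []
        for k in range(0, len(bounds) - 1, 2):
            exons.append((s0 + int(bounds[k]) + 1, s0 + int(bounds[k + 1])))  # 1-based incl
        gene_rows.append((gene_id, chrom, s0 + 1, e0, strand, exons))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand", "exons"])

    te_rows = []
    for ti in range(n_tes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = len(genome[chrom])
        tlen = int(rng.integers(200, 801))
        s = int(rng.integers(0, L - tlen))
        te_rows.append((f"TE{ti + 1:03d}", chrom, s + 1, s + tlen,
                        "+" if rng.random() < 0.5 else "-"))
    tes = pd.DataFrame(te_rows, columns=["te_id", "chrom", "start", "end", "strand"])

    term_map: dict[str, list[str]] = {t: [] for t, _ in TERM_VOCABULARY}
    term_ids = [t for t, _ in TERM_VOCABULARY]
    for gene_id in genes["gene_id"]:
        k = int(rng.integers(1, 6))
        for t in rng.choice(term_ids, size=min(k, len(term_ids)), replace=False):
            term_map[str(t)].append(gene_id)
    term_map = {t: g for t, g in term_map.items() if g}
    return genes, tes, term_map


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\tcaprameth\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for k, (es, ee) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tcaprameth\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n")


def read_gff3(path) -> pd.DataFrame:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[attr["ID"]] = dict(gene_id=attr["ID"], chrom=chrom,
                                         start=int(start), end=int(end),
                                         strand=strand, exons=[])
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent in genes:
                    genes[parent]["exons"].append((int(start), int(end)))
    for g in genes.values():
        g["exons"].sort()
    return pd.DataFrame(list(genes.values()),
                        columns=["gene_id", "chrom", "start", "end", "strand", "exons"])


def write_bed(df: pd.DataFrame, path, name_col: str | None = None,
              coords: str = "1-based") -> None:
    """BED6 (0-based half-open) from an interval frame.

    ``coords="1-based"`` for frames holding 1-based inclusive intervals
    (genes, TEs, DMRs); ``coords="0-based"`` for already half-open intervals
    (CGIs from :func:`generate_genome`).
    """
    off = 1 if coords == "1-based" else 0
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            d = row._asdict()
            name = d.get(name_col) if name_col else d.get("name")
            if name is None:
                name = f"feat{i + 1}"
            fh.write(f"{d['chrom']}\t{int(d['start']) - off}\t{int(d['end'])}\t"
                     f"{name}\t0\t{d.get('strand', '+')}\n")


def write_gmt(term_map: Mapping[str, Sequence[str]], path) -> None:
    desc = dict(TERM_VOCABULARY)
    with open(path, "w") as fh:
        for term, members in term_map.items():
            fh.write("\t".join([term, desc.get(term, term), *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                out[f[0]] = f[2:]
    return out


# ---------------------------------------------------------------------------
# methylomes


def _layout_segments(chrom_len: int, fixed_dmrs: list[tuple[int, int]],
                     rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """Alternate sea/valley segments, with valleys guarding each fixed DMR.

    ``fixed_dmrs`` are 0-based half-open, sorted, non-adjacent.  Returns a
    list of (start, end, kind) covering [0, chrom_len), kind in
    {"sea", "valley", "dmr<i>"}.
    """
    segs: list[tuple[int, int, str]] = []

    def fill(a: int, b: int) -> None:
        """Fill [a,b) with valley/sea alternation starting and ending in valley."""
        pos = a
        want_valley = True
        while pos < b:
            if want_valley:
                ln = int(rng.integers(400, 901))
            else:
                ln = int(rng.integers(2000, 8001))
            nxt_valley = int(rng.integers(400, 901))
            if not want_valley and pos + ln + nxt_valley > b:
                ln = max(b - pos - nxt_valley, 0)  # shrink last sea to leave a valley
            end = min(pos + ln, b)
            if end > pos:
                segs.append((pos, end, "valley" if want_valley else "sea"))
            pos = end
            want_valley = not want_valley

    cursor = 0
    for i, (ds, de) in enumerate(fixed_dmrs):
        fill(cursor, ds)
        if segs and segs[-1][2] == "sea":  # guarantee a valley guard before the DMR
            s, e, _ = segs.pop()
            mid = max(s, e - int(rng.integers(400, 901)))
            if mid > s:
                segs.append((s, mid, "sea"))
            segs.append((mid, e, "valley"))
        segs.append((ds, de, f"dmr{i}"))
        cursor = de
    fill(cursor, chrom_len)
    return segs


def generate_methylomes(
    genome: Mapping[str, str],
    n_per_group: int = 2,
    cg_level: float = 0.7,
    chg_level: float = 0.05,
    chh_level: float = 0.03,
    n_dmr: int = 0,
    dmr_delta: float = 0.5,
    dmr_length: int = 500,
    dmr_low_level: float = 0.3,
    mean_depth: float = 30.0,
    seed: int = 0,
    dmr_regions: Sequence[tuple[str, int, int, str]] | None = None,
    group_names: tuple[str, str] = ("P0-GM", "F1-GM"),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample bisulfite call tables with planted DMRs and a truth table.

    ``dmr_regions``, if given, pins the planted intervals explicitly as
    (chrom, start, end, direction) with 1-based inclusive coordinates and
    direction in {"hyper", "hypo"} (group 2 relative to group 1); otherwise
    ``n_dmr`` regions of ``dmr_length`` bp are placed at random sea domains,
    alternating hyper/hypo.  Group 1 samples are named
    ``<group1>-1..n``, group 2 likewise.  Sites with zero sampled coverage
    are omitted from the tables.  Truth table columns: dmr_id, chrom, start,
    end (1-based inclusive), context, direction, delta.
    """
    for name, lev in (("cg_level", cg_level), ("chg_level", chg_level),
                      ("chh_level", chh_level), ("dmr_low_level", dmr_low_level)):
        if not 0 < lev < 1:
            raise ValueError(f"{name} must be in (0, 1), got {lev}")
    if not 0 < dmr_low_level + dmr_delta <= 1:
        raise ValueError(
            f"dmr_low_level + dmr_delta = {dmr_low_level + dmr_delta} outside (0, 1]")
    if dmr_regions is None and n_dmr > 0 and not 40 <= dmr_length <= 10_000:
        raise ValueError("dmr_length must lie in [40, 10000]")

    rng = np.random.default_rng(seed)

    # pin or place DMR intervals (0-based half-open internally)
    fixed: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome}
    if dmr_regions is not None:
        for chrom, s1, e1, direction in dmr_regions:
            if direction not in ("hyper", "hypo"):
                raise ValueError(f"direction must be hyper/hypo, got {direction!r}")
            fixed[chrom].append((int(s1) - 1, int(e1), direction))
    elif n_dmr > 0:
        chroms = list(genome)
        per = [n_dmr // len(chroms) + (1 if i < n_dmr % len(chroms) else 0)
               for i in range(len(chroms))]
        d_idx = 0
        for chrom, k in zip(chroms, per):
            L = len(genome[chrom])
            # quasi-regular anchors keep planted regions well separated
            anchors = np.linspace(2000, L - dmr_length - 2000, max(k, 1)).astype(int)
            if k * (dmr_length + 1600) > L - 4000:
                raise ValueError(f"chromosome {chrom} too small for {k} planted DMRs")
            for a in anchors[:k]:
                start = int(a + rng.integers(0, 500))
                direction = "hyper" if d_idx % 2 == 0 else "hypo"
                fixed[chrom].append((start, start + dmr_length, direction))
                d_idx += 1
    for c in fixed:
        fixed[c].sort()

    # classify all cytosines and assign per-site mean levels
    truth_rows = []
    site_frames = []
    dmr_counter = 0
    for chrom, seq in genome.items():
        sites = classify_all_cytosines(seq, chrom)
        segs = _layout_segments(len(seq), [(s, e) for s, e, _ in fixed[chrom]], rng)
        seg_start = np.array([s for s, _, _ in segs])
        seg_end = np.array([e for _, e, _ in segs])
        seg_kind = [k for _, _, k in segs]
        pos = sites["pos"].to_numpy()
        seg_idx = np.searchsorted(seg_start, pos, side="right") - 1
        seg_idx = np.clip(seg_idx, 0, len(segs) - 1)
        in_seg = (pos >= seg_start[seg_idx]) & (pos < seg_end[seg_idx])
        kind = np.array([seg_kind[i] if ok else "sea"
                         for i, ok in zip(seg_idx, in_seg)], dtype=object)
        sites = sites.assign(kind=kind)

        is_cg = (sites["context"] == "CG").to_numpy()
        is_sea = is_cg & (sites["kind"] == "sea").to_numpy()
        is_val = is_cg & (sites["kind"] == "valley").to_numpy()
        n_sea, n_val = int(is_sea.sum()), int(is_val.sum())
        if n_sea == 0:
            sea_level = cg_level
        else:
            sea_level = (cg_level * (n_sea + n_val) - VALLEY_LEVEL * n_val) / n_sea
        if not 0.01 < sea_level < 0.995:
            raise ValueError(
                f"cg_level {cg_level} unreachable with valley landscape "
                f"(implied sea level {sea_level:.3f})")

        mean1 = np.where(sites["context"] == "CHG", chg_level,
                         np.where(sites["context"] == "CHH", chh_level,
                                  np.where(is_val, VALLEY_LEVEL, sea_level)))
        mean2 = mean1.copy()
        dmr_mask = np.zeros(len(sites), dtype=bool)
        for i, (s0, e0, direction) in enumerate(fixed[chrom]):
            m = is_cg & (pos >= s0) & (pos < e0)
            dmr_mask |= m
            lo, hi = dmr_low_level, dmr_low_level + dmr_delta
            g1, g2 = (lo, hi) if direction == "hyper" else (hi, lo)
            mean1[m] = g1
            mean2[m] = g2
            truth_rows.append((f"dmr{dmr_counter + 1:04d}", chrom, s0 + 1, e0,
                               "CG", direction, dmr_delta))
            dmr_counter += 1

        c = BETA_CONCENTRATION
        level1 = rng.beta(np.clip(mean1 * c, 1e-3, None),
                          np.clip((1 - mean1) * c, 1e-3, None))
        # outside DMRs both groups share the same per-site true level
        level2 = level1.copy()
        if dmr_mask.any():
            level2[dmr_mask] = rng.beta(
                np.clip(mean2[dmr_mask] * c, 1e-3, None),
                np.clip((1 - mean2[dmr_mask]) * c, 1e-3, None))
        site_frames.append(sites.assign(level1=level1, level2=level2))

    all_sites = pd.concat(site_frames, ignore_index=True)
    samples: dict[str, pd.DataFrame] = {}
    for gi, gname in enumerate(group_names):
        levels = all_sites["level1"] if gi == 0 else all_sites["level2"]
        for si in range(n_per_group):
            cov = rng.poisson(mean_depth, size=len(all_sites))
            meth = rng.binomial(cov, levels.to_numpy())
            keep = cov > 0
            samples[f"{gname}-{si + 1}"] = pd.DataFrame({
                "chrom": all_sites["chrom"].to_numpy()[keep],
                "pos": all_sites["pos"].to_numpy()[keep] + 1,  # 1-based in tables
                "strand": all_sites["strand"].to_numpy()[keep],
                "context": all_sites["context"].to_numpy()[keep],
                "meth_depth": meth[keep],
                "total_depth": cov[keep],
            })
    dmr_truth = pd.DataFrame(truth_rows, columns=[
        "dmr_id", "chrom", "start", "end", "context", "direction", "delta"])
    return samples, dmr_truth


# ---------------------------------------------------------------------------
# expression counts


def generate_counts(
    genes: pd.DataFrame,
    n_per_group: int = 2,
    baseline_mean: float = 500.0,
    dispersion: float = 0.05,
    n_de: int = 10,
    de_log2fc: float = 2.0,
    linked_fraction: float = 0.0,
    seed: int = 0,
    gene_dmr_links: pd.DataFrame | None = None,
    group_names: tuple[str, str] = ("P0-GM", "F1-GM"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB-distributed count matrix with planted DE genes and DMR-linked genes.

    ``gene_dmr_links`` (columns gene_id, dmr_id, direction) lists genes with
    a planted DMR in their promoter or body +- 2 kb; ``linked_fraction`` of
    the ``n_de`` DE genes are drawn from it with the repressive sign
    convention (hypermethylated promoter -> expression down, hypomethylated
    -> up).  Returns (counts, de_truth, linked_genes); counts are genes x
    samples with gene ids as index.
    """
    if n_de > len(genes):
        raise ValueError(f"n_de {n_de} exceeds gene count {len(genes)}")
    rng = np.random.default_rng(seed)
    gene_ids = list(genes["gene_id"])
    base = np.exp(rng.normal(np.log(baseline_mean), 0.5, size=len(gene_ids)))

    lfc = np.zeros(len(gene_ids))
    linked_rows = []
    de_ids: list[str] = []
    if n_de > 0 and de_log2fc != 0:
        n_linked = int(round(linked_fraction * n_de))
        if n_linked > 0:
            if gene_dmr_links is None or len(gene_dmr_links) == 0:
                raise ValueError("linked genes requested but no gene-DMR links supplied")
            pool = gene_dmr_links.drop_duplicates("gene_id")
            if n_linked > len(pool):
                raise ValueError(
                    f"{n_linked} linked genes requested but only {len(pool)} genes "
                    "have a planted DMR nearby")
            chosen = pool.iloc[
                rng.choice(len(pool), size=n_linked, replace=False)]
            for row in chosen.itertuples(index=False):
                sign = -1 if row.direction == "hyper" else +1
                gi = gene_ids.index(row.gene_id)
                lfc[gi] = sign * abs(de_log2fc)
                de_ids.append(row.gene_id)
                linked_rows.append((row.gene_id, row.dmr_id, sign))
        rest = [g for g in gene_ids if g not in de_ids]
        extra = rng.choice(len(rest), size=n_de - n_linked, replace=False)
        for j, k in enumerate(extra):
            gi = gene_ids.index(rest[int(k)])
            lfc[gi] = abs(de_log2fc) * (1 if j % 2 == 0 else -1)
            de_ids.append(rest[int(k)])

    sample_names = [f"{g}-{i + 1}" for g in group_names for i in range(n_per_group)]
    mat = np.zeros((len(gene_ids), len(sample_names)), dtype=np.int64)
    for j, name in enumerate(sample_names):
        mu = base * (2.0 ** lfc if j >= n_per_group else 1.0)
        if dispersion > 0:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mu)
            mat[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            mat[:, j] = rng.poisson(mu)
    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_names)
    de_truth = pd.DataFrame(
        [(g, lfc[gene_ids.index(g)]) for g in de_ids],
        columns=["gene_id", "true_log2fc"])
    linked_genes = pd.DataFrame(linked_rows, columns=["gene_id", "dmr_id", "link_sign"])
    return counts, de_truth, linked_genes


# ---------------------------------------------------------------------------
# raw reads


def generate_reads(
    n_reads: int = 1000,
    read_length: int = 100,
    frac_n_fail: float = 0.1,
    frac_q_fail: float = 0.1,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Reads with known QC fate: pass / n_fail (>10% N) / q_fail (>40% Q<=20).

    Returns (records, labels): records are (read_id, sequence, quality
    string, Phred+33); labels has columns read_id, label.  Exactly
    ``round(frac * n_reads)`` reads carry each failure label.  Pass reads
    include boundary cases sitting exactly at 10% N and at 40% low-quality
    bases (which the strict > rules must keep).
    """
    if read_length < 10:
        raise ValueError("read_length must be >= 10")
    for f in (frac_n_fail, frac_q_fail):
        if not 0 <= f <= 1:
            raise ValueError("failure fractions must lie in [0, 1]")
    if frac_n_fail + frac_q_fail > 1:
        raise ValueError("failure fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_n = int(round(frac_n_fail * n_reads))
    n_q = int(round(frac_q_fail * n_reads))
    n_pass = n_reads - n_n - n_q
    max_n = read_length // 10  # floor(10% of L): allowed N count for a pass read
    max_lowq = int(0.4 * read_length)  # allowed Q<=20 count for a pass read

    bases = np.array(list("ACGT"))
    records = []
    labels = []

    def seq_qual(n_count: int, lowq_count: int) -> tuple[str, str]:
        seq = rng.choice(bases, size=read_length)
        qual = rng.integers(30, 41, size=read_length)  # high quality baseline
        pos = rng.permutation(read_length)
        npos = pos[:n_count]
        seq[npos] = "N"
        qual[npos] = 2  # N bases are low quality, and count toward the low-Q rule
        extra = max(lowq_count - n_count, 0)
        qpos = pos[n_count:n_count + extra]
        qual[qpos] = rng.integers(3, 21, size=extra)
        return "".join(seq), "".join(chr(q + 33) for q in qual)

    idx = 0
    for _ in range(n_n):
        k = int(rng.integers(max_n + 1, max(max_n + 2, read_length // 3 + 1)))
        s, q = seq_qual(k, k)
        records.append((f"read{idx:05d}", s, q))
        labels.append("n_fail")
        idx += 1
    for _ in range(n_q):
        k = int(rng.integers(max_lowq + 1, max(max_lowq + 2, int(0.8 * read_length))))
        s, q = seq_qual(0, 0)
        # overwrite: no Ns, k low-quality bases
        qual = np.array([ord(c) - 33 for c in q])
        qpos = rng.permutation(read_length)[:k]
        qual[qpos] = rng.integers(2, 21, size=k)
        records.append((f"read{idx:05d}", s, "".join(chr(v + 33) for v in qual)))
        labels.append("q_fail")
        idx += 1
    for j in range(n_pass):
        if j == 0 and n_pass > 0:
            k_n, k_q = max_n, max_n  # boundary: exactly 10% N
        elif j == 1 and n_pass > 1:
            k_n, k_q = 0, max_lowq  # boundary: exactly 40% low-quality
        else:
            k_n = int(rng.integers(0, max_n + 1))
            k_q = int(rng.integers(k_n, max_lowq + 1))
        s, q = seq_qual(k_n, k_q)
        records.append((f"read{idx:05d}", s, q))
        labels.append("pass")
        idx += 1

    order = rng.permutation(n_reads)
    records = [records[i] for i in order]
    label_df = pd.DataFrame({"read_id": [r[0] for r in records],
                             "label": [labels[i] for i in order]})
    return records, label_df


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
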