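"""End-to-end reproducible run: simulate -> QC -> profile -> DMR -> annotate
-> DE -> integrate -> enrich.

A run is driven by a :class:`RunConfig` (plain YAML on disk), derives every
random stream from one seed, writes all intermediate tables under the
output directory with a provenance header (tool version, config hash,
seed), and produces a machine-readable report of the headline counts:
hyper/hypo DMRs per context, differentially methylated genes, DE-high /
DE-low genes, the four integration cells, and — because the inputs are
simulated with planted truth — recovery scores against that truth.
Rerunning the same config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import caprameth
from caprameth import annotate as ann
from caprameth import dmr as dmrmod
from caprameth import enrichment as enr
from caprameth import expression as expr
from caprameth import profiler, readqc, synthetic

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the published thresholds."""

    seed: int = 0
    outdir: str = "caprameth_run"
    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 150_000
    gc_fraction: float = 0.42
    cgi_density: float = 10.0
    n_genes: int = 24
    n_tes: int = 8
    # methylome
    n_per_group: int = 2
    cg_level: float = 0.7
    chg_level: float = 0.05
    chh_level: float = 0.03
    mean_depth: float = 30.0
    dmr_delta: float = 0.5
    dmr_length: int = 500
    dmr_low_level: float = 0.3
    n_linked_hyper: int = 5
    n_linked_hypo: int = 5
    n_dmr_extra: int = 4
    # expression
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    n_de: int = 12
    de_log2fc: float = 2.0
    # raw reads
    n_reads: int = 500
    read_length: int = 100
    frac_n_fail: float = 0.1
    frac_q_fail: float = 0.1
    # caller thresholds (published defaults)
    dmr_min_total_depth: int = 10
    dmr_min_meth_depth: int = 4
    dmr_max_gap: int = 200
    dmr_min_len: int = 40
    dmr_max_len: int = 10_000
    dmr_min_sites: int = 5
    dmr_min_fold_change: float = 2.0
    dmr_alpha: float = 0.05
    de_alpha_q: float = 0.05
    de_min_abs_log2: float = 1.0
    enrich_alpha: float = 0.05
    groups: tuple = ("P0-GM", "F1-GM")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(d) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        d.pop("outdir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _dmr_params(cfg: RunConfig) -> dmrmod.DMRParams:
    return dmrmod.DMRParams(
        min_total_depth=cfg.dmr_min_total_depth,
        min_meth_depth=cfg.dmr_min_meth_depth,
        max_gap=cfg.dmr_max_gap, min_len=cfg.dmr_min_len,
        max_len=cfg.dmr_max_len, min_sites=cfg.dmr_min_sites,
        min_fold_change=cfg.dmr_min_fold_change, alpha=cfg.dmr_alpha)


def plan_dmr_regions(genes: pd.DataFrame, genome: dict, cfg: RunConfig,
                     rng: np.random.Generator):
    """Choose linked-gene promoter DMRs plus extra unlinked regions.

    Returns (regions, designated): regions as (chrom, start, end, direction)
    1-based inclusive for the methylome generator, and the designated
    (gene_id, direction) pairs whose promoters carry the planted DMRs.
    """
    n_linked = cfg.n_linked_hyper + cfg.n_linked_hypo
    if n_linked > len(genes):
        raise ValueError("more linked genes requested than genes available")
    pick = rng.choice(len(genes), size=n_linked, replace=False)
    regions, designated = [], []
    for j, gi in enumerate(pick):
        g = genes.iloc[int(gi)]
        direction = "hyper" if j < cfg.n_linked_hyper else "hypo"
        gm = ann.GeneModel(g.gene_id, g.chrom, int(g.start), int(g.end), g.strand)
        ps, pe = gm.promoter(2000)
        mid = (ps + pe) // 2
        s1 = max(ps, mid - cfg.dmr_length // 2)
        regions.append((g.chrom, s1, s1 + cfg.dmr_length - 1, direction))
        designated.append((g.gene_id, direction))
    # extra unlinked regions in gaps well away from existing regions and genes
    occupied = {c: [] for c in genome}
    for chrom, s, e, _ in regions:
        occupied[chrom].append((s - 1500, e + 1500))
    for g in genes.itertuples(index=False):
        occupied[g.chrom].append((int(g.start) - 2500, int(g.end) + 2500))
    placed = 0
    attempts = 0
    while placed < cfg.n_dmr_extra and attempts < 2000:
        attempts += 1
        chrom = list(genome)[int(rng.integers(0, len(genome)))]
        L = len(genome[chrom])
        s1 = int(rng.integers(2000, L - cfg.dmr_length - 2000))
        e1 = s1 + cfg.dmr_length - 1
        if any(s1 <= oe and e1 >= os_ for os_, oe in occupied[chrom]):
            continue
        direction = "hyper" if placed % 2 == 0 else "hypo"
        regions.append((chrom, s1, e1, direction))
        occupied[chrom].append((s1 - 1500, e1 + 1500))
        placed += 1
    if placed < cfg.n_dmr_extra:
        logger.warning("placed only %d of %d extra DMRs", placed, cfg.n_dmr_extra)
    regions.sort()
    return regions, designated


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain; returns the report dict (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    prov = f"# caprameth {caprameth.__version__} config={chash} seed={cfg.seed}\n"
    base = int(cfg.seed) % (2**31 - 100)
    report: dict = {"config_hash": chash, "seed": cfg.seed}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate:genome")
        genome, cgis = synthetic.generate_genome(
            cfg.n_chrom, cfg.chrom_length, cfg.gc_fraction, cfg.cgi_density,
            seed=base)
        synthetic.write_fasta(genome, out / "genome.fa")
        synthetic.write_bed(cgis, out / "cgi.bed", coords="0-based")

        stage("simulate:annotation")
        genes, tes, term_map = synthetic.generate_annotation(
            genome, cfg.n_genes, cfg.n_tes, seed=base + 1)
        synthetic.write_gff3(genes, out / "genes.gff3")
        synthetic.write_bed(tes, out / "te.bed", name_col="te_id")
        synthetic.write_gmt(term_map, out / "terms.gmt")

        stage("simulate:methylomes")
        rng = np.random.default_rng(base + 2)
        regions, designated = plan_dmr_regions(genes, genome, cfg, rng)
        samples, dmr_truth = synthetic.generate_methylomes(
            genome, n_per_group=cfg.n_per_group, cg_level=cfg.cg_level,
            chg_level=cfg.chg_level, chh_level=cfg.chh_level,
            dmr_delta=cfg.dmr_delta, dmr_low_level=cfg.dmr_low_level,
            mean_depth=cfg.mean_depth, seed=base + 3,
            dmr_regions=regions, group_names=tuple(cfg.groups))
        manifest = {}
        for name, df in samples.items():
            profiler.write_calls(df, out / f"calls.{name}.tsv")
            manifest[name] = name.rsplit("-", 1)[0]
        _write_tsv(dmr_truth, out / "truth.dmrs.tsv", prov)

        stage("simulate:counts")
        truth_links, _, _ = ann.map_dmrs_to_genes(dmr_truth, genes)
        desig = pd.DataFrame(designated, columns=["gene_id", "direction"])
        link_pool = truth_links.merge(desig, on=["gene_id", "direction"]) \
            .drop_duplicates("gene_id")[["gene_id", "dmr_id", "direction"]]
        n_linked = len(desig)
        counts, de_truth, linked_genes = synthetic.generate_counts(
            genes, n_per_group=cfg.n_per_group, baseline_mean=cfg.baseline_mean,
            dispersion=cfg.dispersion, n_de=max(cfg.n_de, n_linked),
            de_log2fc=cfg.de_log2fc,
            linked_fraction=n_linked / max(cfg.n_de, n_linked, 1),
            seed=base + 4, gene_dmr_links=link_pool,
            group_names=tuple(cfg.groups))
        counts.to_csv(out / "counts.tsv", sep="\t")
        _write_tsv(de_truth, out / "truth.de.tsv", prov)
        _write_tsv(linked_genes, out / "truth.linked.tsv", prov)

        stage("simulate:reads+qc")
        reads, labels = synthetic.generate_reads(
            cfg.n_reads, cfg.read_length, cfg.frac_n_fail, cfg.frac_q_fail,
            seed=base + 5)
        synthetic.write_fastq(reads, out / "reads.fastq")
        _write_tsv(labels, out / "truth.reads.tsv", prov)
        qc_report = readqc.filter_reads(out / "reads.fastq", out / "reads.clean.fastq")
        report["read_qc"] = dataclasses.asdict(qc_report)

        stage("profile")
        pooled = pd.concat(samples.values(), ignore_index=True)
        summary = profiler.genome_summary(pooled, scope="genome")
        _write_tsv(summary, out / "methylation.summary.tsv", prov)
        per_chrom = profiler.genome_summary(pooled, scope="chromosome")
        _write_tsv(per_chrom, out / "methylation.per_chrom.tsv", prov)
        windows = profiler.window_levels(pooled, window=2000)
        _write_tsv(windows, out / "methylation.windows.tsv", prov)
        profile = profiler.metagene_profile(pooled, genes)
        _write_tsv(profile, out / "methylation.metagene.tsv", prov)
        report["cg_level_genomewide"] = float(
            summary.loc[summary["context"] == "CG", "level"].iloc[0])

        stage("dmr")
        dmrs, dmr_summary, tested = dmrmod.call_dmrs(
            samples, manifest, _dmr_params(cfg), groups=tuple(cfg.groups))
        _write_tsv(dmrs, out / "dmrs.tsv", prov)
        _write_tsv(dmr_summary, out / "dmrs.summary.tsv", prov)
        _write_tsv(dmrmod.length_distribution(dmrs), out / "dmrs.lengths.tsv", prov)
        report["dmrs"] = {
            r.context: {"hyper": int(r.n_hyper), "hypo": int(r.n_hypo)}
            for r in dmr_summary.itertuples(index=False)}
        sens, prec = score_dmr_recovery(dmrs, dmr_truth)
        report["dmr_recovery"] = {"sensitivity": sens, "precision": prec}

        stage("annotate")
        assignments, dm_sets, te_assign = ann.map_dmrs_to_genes(dmrs, genes, tes)
        _write_tsv(assignments, out / "dmr_genes.tsv", prov)
        _write_tsv(te_assign, out / "dmr_tes.tsv", prov)
        per_dmr, feat_counts = ann.feature_distribution(dmrs, genes, cgis)
        _write_tsv(per_dmr, out / "dmr_features.tsv", prov)
        _write_tsv(feat_counts, out / "dmr_feature_counts.tsv", prov)
        report["dm_genes"] = {"hyper": sorted(dm_sets["hyper"]),
                              "hypo": sorted(dm_sets["hypo"])}

        stage("de")
        de = expr.de_test(counts, manifest, cfg.de_alpha_q, cfg.de_min_abs_log2,
                          groups=tuple(cfg.groups))
        lengths = genes.set_index("gene_id")["exons"].map(
            lambda ex: sum(e - s + 1 for s, e in ex))
        fpkm = expr.add_fpkm(counts, lengths)
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        _write_tsv(de, out / "de.tsv", prov)
        de_high = sorted(de.loc[de["call"] == "DE-high", "gene_id"])
        de_low = sorted(de.loc[de["call"] == "DE-low", "gene_id"])
        report["de"] = {"DE-high": de_high, "DE-low": de_low}

        stage("integrate")
        table = enr.integrate(dm_sets["hyper"], dm_sets["hypo"], de_high, de_low)
        venn = table.venn_counts()
        report["venn"] = venn
        venn_df = pd.DataFrame(
            [(k, v, ";".join(sorted(s))) for (k, v), s in
             zip(venn.items(), [table.hyper_low, table.hyper_high,
                                table.hypo_low, table.hypo_high])],
            columns=["cell", "count", "genes"])
        _write_tsv(venn_df, out / "venn.tsv", prov)

        stage("enrich")
        background = sorted(genes["gene_id"])
        dm_all = sorted(dm_sets["hyper"] | dm_sets["hypo"])
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            enr_dm = enr.enrich(dm_all, background, term_map, cfg.enrich_alpha)
            tested_genes = sorted(de.loc[de["p"].notna(), "gene_id"])
            enr_de = enr.enrich(de_high + de_low, tested_genes, term_map,
                                cfg.enrich_alpha)
        _write_tsv(enr_dm, out / "enrichment.dm_genes.tsv", prov)
        _write_tsv(enr_de, out / "enrichment.degs.tsv", prov)
        report["enrichment"] = {
            "dm_genes_significant": int(enr_dm["significant"].sum()) if len(enr_dm) else 0,
            "degs_significant": int(enr_de["significant"].sum()) if len(enr_de) else 0}

        # linked-gene scoring against truth
        linked_cells = {}
        for row in linked_genes.itertuples(index=False):
            want = "DM-high∩DE-low" if row.link_sign < 0 else "DM-low∩DE-high"
            got = [cell for cell, s in
                   (("DM-high∩DE-low", table.hyper_low),
                    ("DM-high∩DE-high", table.hyper_high),
                    ("DM-low∩DE-low", table.hypo_low),
                    ("DM-low∩DE-high", table.hypo_high)) if row.gene_id in s]
            linked_cells[row.gene_id] = {"expected": want, "observed": got}
        report["linked_genes"] = linked_cells
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    cfg.to_yaml(out / "config.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def score_dmr_recovery(dmrs: pd.DataFrame, truth: pd.DataFrame,
                       min_overlap: float = 0.5) -> tuple[float, float]:
    """Sensitivity and precision of called DMRs against planted truth.

    A planted region is recovered when some called DMR of the same direction
    covers >= ``min_overlap`` of it; a called DMR is correct when
    >= ``min_overlap`` of the planted region it hits is covered, with
    matching direction.  Returns (sensitivity, precision); NaN when the
    denominator set is empty.
    """
    def covered(t, d):
        ov = max(0, min(t.end, d.end) - max(t.start, d.start) + 1)
        return ov / (t.end - t.start + 1)

    recovered = 0
    for t in truth.itertuples(index=False):
        if any(d.direction == t.direction and d.chrom == t.chrom
               and covered(t, d) >= min_overlap
               for d in dmrs.itertuples(index=False)):
            recovered += 1
    correct = 0
    for d in dmrs.itertuples(index=False):
        if any(t.direction == d.direction and t.chrom == d.chrom
               and covered(t, d) >= min_overlap
               for t in truth.itertuples(index=False)):
            correct += 1
    sens = recovered / len(truth) if len(truth) else float("nan")
    prec = correct / len(dmrs) if len(dmrs) else float("nan")
    return sens, prec
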