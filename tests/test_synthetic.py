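"""Contracts of the planted-truth simulator."""

import numpy as np
import pandas as pd
import pytest

from caprameth import synthetic
from caprameth.profiler import genome_summary


class TestGenome:
    def test_sizes_and_alphabet(self, genome100k):
        genome, cgis = genome100k
        assert set(genome) == {"chr1"}
        seq = genome["chr1"]
        assert len(seq) == 100_000
        assert set(seq) <= set("ACGT")
        assert len(cgis) == 1  # 10 islands/Mb at 100 kb

    def test_gc_fraction_within_binomial_bound(self, genome100k):
        genome, _ = genome100k
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.42) < 0.02

    def test_seed_reproducibility_bytes(self):
        g1, c1 = synthetic.generate_genome(1, 10_000, seed=7)
        g2, c2 = synthetic.generate_genome(1, 10_000, seed=7)
        assert g1 == g2
        pd.testing.assert_frame_equal(c1, c2)

    def test_cgi_cpg_enriched(self, genome100k):
        genome, cgis = genome100k
        seq = genome["chr1"]
        bg_cpg = seq.count("CG") / len(seq)
        for c in cgis.itertuples(index=False):
            island = seq[c.start:c.end]
            assert island.count("CG") / len(island) > bg_cpg

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_genome(1, 500)
        with pytest.raises(ValueError):
            synthetic.generate_genome(1, 20_000, gc_fraction=1.5)


class TestAnnotation:
    def test_gene_contracts(self, small_annotation, genome100k):
        genes, tes, term_map = small_annotation
        genome, _ = genome100k
        assert len(genes) == 10
        assert set(genes["strand"]) <= {"+", "-"}
        # non-overlapping, 2 kb clearance from ends
        g = genes.sort_values("start")
        assert (g["start"].iloc[1:].to_numpy() > g["end"].iloc[:-1].to_numpy()).all()
        assert g["start"].min() > 2000
        assert g["end"].max() < len(genome["chr1"]) - 2000
        for ex in genes["exons"]:
            assert len(ex) >= 1
        mapped = set().union(*term_map.values())
        assert set(genes["gene_id"]) <= mapped

    def test_too_small_genome_rejected(self):
        genome, _ = synthetic.generate_genome(1, 10_000, seed=1)
        with pytest.raises(ValueError, match="too small"):
            synthetic.generate_annotation(genome, n_genes=50, seed=1)


class TestMethylomes:
    def test_baseline_recovery(self, null_methylomes):
        samples, _ = null_methylomes
        pooled = pd.concat(samples.values(), ignore_index=True)
        summ = genome_summary(pooled).set_index("context")["level"]
        assert abs(summ["CG"] - 0.70) < 0.02
        assert abs(summ["CHG"] - 0.05) < 0.01
        assert abs(summ["CHH"] - 0.03) < 0.01

    def test_cg_methylated_sites_dominate(self, null_methylomes):
        # "methylated site" by the operational eligibility rule
        # (depth > 10, methylated reads > 4); sporadic single reads on the
        # dense CHH background do not make a site methylated
        samples, _ = null_methylomes
        df = next(iter(samples.values()))
        meth = df[(df["meth_depth"] > 4) & (df["total_depth"] > 10)]
        counts = meth["context"].value_counts()
        assert counts["CG"] > counts.get("CHG", 0)
        assert counts["CG"] > counts.get("CHH", 0)

    def test_planted_dmr_group_difference(self, planted_methylomes):
        samples, truth, manifest = planted_methylomes
        pooled = {g: pd.concat([df for n, df in samples.items() if manifest[n] == g])
                  for g in ("P0-GM", "F1-GM")}
        for t in truth.itertuples(index=False):
            lev = {}
            for g, df in pooled.items():
                sub = df[(df["chrom"] == t.chrom) & (df["pos"] >= t.start)
                         & (df["pos"] <= t.end) & (df["context"] == "CG")]
                lev[g] = sub["meth_depth"].sum() / sub["total_depth"].sum()
            diff = lev["F1-GM"] - lev["P0-GM"]
            assert abs(diff) >= 0.4
            assert (diff > 0) == (t.direction == "hyper")

    def test_truth_levels_satisfy_fold_change(self, planted_methylomes):
        # the planted true levels themselves give fold change > 2
        _, truth, _ = planted_methylomes
        lo, hi = 0.3, 0.8
        assert hi / lo > 2
        assert set(truth["direction"]) == {"hyper", "hypo"}

    def test_zero_coverage_rows_omitted(self, null_methylomes):
        samples, _ = null_methylomes
        for df in samples.values():
            assert (df["total_depth"] > 0).all()
            assert (df["meth_depth"] <= df["total_depth"]).all()

    def test_invalid_delta_rejected(self, genome100k):
        genome, _ = genome100k
        with pytest.raises(ValueError):
            synthetic.generate_methylomes(genome, n_dmr=2, dmr_delta=0.9,
                                          dmr_low_level=0.3, seed=1)

    def test_determinism(self):
        genome, _ = synthetic.generate_genome(1, 20_000, seed=9)
        s1, t1 = synthetic.generate_methylomes(genome, n_dmr=2, seed=9)
        s2, t2 = synthetic.generate_methylomes(genome, n_dmr=2, seed=9)
        for name in s1:
            pd.testing.assert_frame_equal(s1[name], s2[name])
        pd.testing.assert_frame_equal(t1, t2)


class TestCounts:
    def _genes(self, n=50):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)]})

    def test_null_truth_empty(self):
        _, de_truth, _ = synthetic.generate_counts(
            self._genes(), n_de=5, de_log2fc=0.0, seed=1)
        assert de_truth.empty

    def test_linked_gene_sign_convention(self):
        links = pd.DataFrame({"gene_id": ["g0", "g1"], "dmr_id": ["d1", "d2"],
                              "direction": ["hyper", "hypo"]})
        counts, de_truth, linked = synthetic.generate_counts(
            self._genes(), n_de=2, de_log2fc=2.0, linked_fraction=1.0,
            gene_dmr_links=links, seed=2)
        merged = linked.merge(de_truth, on="gene_id")
        for row in merged.itertuples(index=False):
            assert np.sign(row.true_log2fc) == row.link_sign
        hyper_gene = linked.loc[linked["dmr_id"] == "d1", "gene_id"].iloc[0]
        assert de_truth.set_index("gene_id").loc[hyper_gene, "true_log2fc"] == -2.0

    def test_determinism_and_errors(self):
        c1, *_ = synthetic.generate_counts(self._genes(), seed=3)
        c2, *_ = synthetic.generate_counts(self._genes(), seed=3)
        pd.testing.assert_frame_equal(c1, c2)
        with pytest.raises(ValueError):
            synthetic.generate_counts(self._genes(5), n_de=10, seed=1)
        with pytest.raises(ValueError, match="linked"):
            synthetic.generate_counts(self._genes(), n_de=4, linked_fraction=0.5,
                                      gene_dmr_links=None, seed=1)


class TestReads:
    def test_label_counts_and_composition(self):
        records, labels = synthetic.generate_reads(1000, 100, 0.1, 0.1, seed=5)
        assert len(records) == 1000
        vc = labels["label"].value_counts()
        assert vc["n_fail"] == 100 and vc["q_fail"] == 100 and vc["pass"] == 800
        by_id = {rid: (seq, qual) for rid, seq, qual in records}
        lab = dict(zip(labels["read_id"], labels["label"]))
        for rid, (seq, qual) in by_id.items():
            n_n = sum(1 for b in seq if b not in "ACGT")
            n_lowq = sum(1 for c in qual if ord(c) - 33 <= 20)
            if lab[rid] == "n_fail":
                assert n_n >= 11
            elif lab[rid] == "q_fail":
                assert n_n <= 10 and n_lowq >= 41
            else:
                assert n_n <= 10 and n_lowq <= 40

    def test_boundary_pass_reads_exist(self):
        records, labels = synthetic.generate_reads(100, 100, 0.1, 0.1, seed=6)
        by_id = {rid: (seq, qual) for rid, seq, qual in records}
        passing = [by_id[r] for r, l in zip(labels["read_id"], labels["label"])
                   if l == "pass"]
        assert any(sum(1 for b in s if b not in "ACGT") == 10 for s, _ in passing)
        assert any(sum(1 for c in q if ord(c) - 33 <= 20) == 40 for _, q in passing)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            synthetic.generate_reads(10, read_length=5)
        with pytest.raises(ValueError):
            synthetic.generate_reads(10, frac_n_fail=0.7, frac_q_fail=0.7)
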