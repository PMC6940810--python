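"""Context classification and methylation-level profiling."""

import numpy as np
import pandas as pd
import pytest

from caprameth import profiler
from caprameth.profiler import (classify_all_cytosines, classify_context,
                                genome_summary, merge_cpg, metagene_profile,
                                revcomp, site_level, window_levels)


def brute_context(seq: str, pos: int, strand: str):
    """Independent oracle: operate literally on the strand's own sequence."""
    if strand == "-":
        rc = revcomp(seq)
        return brute_context(rc, len(seq) - 1 - pos, "+")
    if seq[pos] != "C":
        raise ValueError("not a C")
    tri = seq[pos:pos + 3]
    if len(tri) < 3 or any(b not in "ACGT" for b in tri):
        return None
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


class TestClassifyContext:
    def test_worked_examples(self):
        g = {"c": "ACGTT"}
        assert classify_context(g, "c", 1, "+") == "CG"
        g = {"c": "ACAGT"}
        assert classify_context(g, "c", 1, "+") == "CHG"
        g = {"c": "ACTTA"}
        assert classify_context(g, "c", 1, "+") == "CHH"

    def test_all_16_dinucleotide_completions(self):
        for b1 in "ACGT":
            for b2 in "ACGT":
                seq = "C" + b1 + b2
                got = classify_context({"c": seq}, "c", 0, "+")
                assert got == brute_context(seq, 0, "+")

    def test_minus_strand_and_edges(self):
        seq = "TTCGA"  # G at index 3 is a minus-strand C followed by CG..
        assert classify_context({"c": seq}, "c", 3, "-") == brute_context(seq, 3, "-")
        assert classify_context({"c": "AACG"}, "c", 2, "+") is None  # runs off end
        assert classify_context({"c": "GAA"}, "c", 0, "-") is None
        with pytest.raises(ValueError):
            classify_context({"c": "AAAA"}, "c", 1, "+")

    def test_vectorised_matches_bruteforce_on_random_sequence(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        table = classify_all_cytosines(seq)
        expected = []
        for i, b in enumerate(seq):
            if b == "C":
                ctx = brute_context(seq, i, "+")
                if ctx:
                    expected.append((i, "+", ctx))
            if b == "G":
                ctx = brute_context(seq, i, "-")
                if ctx:
                    expected.append((i, "-", ctx))
        got = list(zip(table["pos"], table["strand"], table["context"]))
        assert sorted(got) == sorted(expected)


class TestSiteLevel:
    @pytest.mark.parametrize("meth,total,expected",
                             [(4, 10, 0.4), (0, 10, 0.0), (10, 10, 1.0)])
    def test_values(self, meth, total, expected):
        assert site_level(meth, total) == expected

    def test_undefined_at_zero_depth(self):
        with pytest.raises(ValueError):
            site_level(0, 0)


def _calls(rows):
    return pd.DataFrame(rows, columns=profiler.CALL_COLUMNS)


class TestGenomeSummary:
    def test_depth_weighted_pooling(self):
        calls = _calls([("c", 10, "+", "CG", 4, 10), ("c", 20, "+", "CG", 6, 10)])
        summ = genome_summary(calls).set_index("context")
        assert summ.loc["CG", "level"] == 0.5
        assert np.isnan(summ.loc["CHG", "level"])
        assert summ.loc["CHG", "n_sites"] == 0

    def test_fully_methylated_conserved(self):
        calls = _calls([("c", i, "+", ctx, 8, 8)
                        for i, ctx in enumerate(["CG", "CHG", "CHH"], 1)])
        summ = genome_summary(calls)
        assert (summ["level"] == 1.0).all()

    def test_per_chromosome_scope(self):
        calls = _calls([("c1", 1, "+", "CG", 1, 10), ("c2", 1, "+", "CG", 9, 10)])
        summ = genome_summary(calls, "chromosome")
        cg = summ[summ["context"] == "CG"].set_index("chrom")["level"]
        assert cg["c1"] == 0.1 and cg["c2"] == 0.9


class TestWindows:
    def test_tiling_counts_and_identity(self):
        rng = np.random.default_rng(3)
        pos = rng.choice(np.arange(1, 4001), size=300, replace=False)
        total = rng.integers(1, 40, size=300)
        meth = rng.binomial(total, 0.4)
        calls = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                              "context": "CG", "meth_depth": meth,
                              "total_depth": total})
        win = window_levels(calls, window=2000)
        assert len(win) == 2  # 4 kb chromosome tiles into 2 windows
        # depth-weighted mean of window levels equals the genome-wide level
        pooled = (win["level"] * win["total_depth"]).sum() / win["total_depth"].sum()
        assert pooled == pytest.approx(meth.sum() / total.sum(), abs=1e-12)

    def test_all_unmethylated(self):
        calls = _calls([("c", i, "+", "CG", 0, 5) for i in (1, 2500)])
        win = window_levels(calls, window=2000)
        assert (win["level"] == 0).all()

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            window_levels(_calls([]), window=0)


class TestMetagene:
    def _uniform_calls(self, n=6000, level_num=1, level_den=2):
        pos = np.arange(1, n + 1, 7)
        return pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                             "context": "CG", "meth_depth": level_num,
                             "total_depth": level_den})

    def test_uniform_field_flat_profile(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [2500], "end": [3500],
                              "strand": ["+"]})
        prof = metagene_profile(self._uniform_calls(), feats)
        assert np.allclose(prof["mean_level"], 0.5)

    def test_bin_counts_forced_by_parameters(self):
        feats = pd.DataFrame({"chrom": ["c"], "start": [2500], "end": [2699],
                              "strand": ["+"]})
        prof = metagene_profile(self._uniform_calls(), feats, flank=2000,
                                bin_width=100, body_bins=20)
        up = prof[prof["region"] == "upstream"]
        down = prof[prof["region"] == "downstream"]
        assert up["bin"].max() <= 20 and len(up) == 20
        assert down["bin"].max() <= 20 and len(down) == 20

    def test_strand_reversal_mirrors_bins(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 8001), 900, replace=False))
        calls = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                              "context": "CG",
                              "meth_depth": rng.integers(0, 11, 900),
                              "total_depth": 10})
        plus = pd.DataFrame({"chrom": ["c"], "start": [3000], "end": [4999],
                             "strand": ["+"]})
        minus = plus.assign(strand="-")
        p = metagene_profile(calls, plus).set_index(["region", "bin"])
        m = metagene_profile(calls, minus).set_index(["region", "bin"])
        # upstream bin k on + equals downstream bin (n-k+1) on - and vice versa
        for k in range(1, 21):
            pv = p.loc[("upstream", k), "mean_level"]
            mv = m.loc[("downstream", 21 - k), "mean_level"]
            assert pv == pytest.approx(mv)
        for k in range(1, 21):
            pv = p.loc[("body", k), "mean_level"]
            mv = m.loc[("body", 21 - k), "mean_level"]
            assert pv == pytest.approx(mv)


class TestMergeCpG:
    def test_dyad_strands_summed(self):
        calls = _calls([("c", 10, "+", "CG", 3, 10), ("c", 11, "-", "CG", 5, 10),
                        ("c", 30, "+", "CHH", 1, 10)])
        merged = merge_cpg(calls)
        cg = merged[merged["context"] == "CG"]
        assert len(cg) == 1
        assert cg.iloc[0]["pos"] == 10
        assert cg.iloc[0]["meth_depth"] == 8 and cg.iloc[0]["total_depth"] == 20
        assert (merged["context"] == "CHH").sum() == 1
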