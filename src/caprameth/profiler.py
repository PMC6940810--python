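"""Cytosine context classification and methylation-level profiling.

A bisulfite call table records, for every covered cytosine, how many reads
support methylation and how many reads cover the site.  The methylation
level of a site is the fraction of supporting reads; pooled levels over a
scope (genome, chromosome, window, region) are depth-weighted:
``sum(meth_depth) / sum(total_depth)``.

Sequence context is determined by the two bases immediately 3' of the
cytosine on its own strand: CG, CHG or CHH with H = A, C or T.  On the
minus strand the 3' direction runs toward lower plus-strand coordinates and
context bases are read as complements.

Coordinates are 0-based half-open internally; emitted and consumed call
tables use 1-based positions (column ``pos``).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_depth", "total_depth"]
CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at 0-based ``pos`` on ``strand`` of ``chrom``.

    Returns ``"CG"``, ``"CHG"`` or ``"CHH"``, or ``None`` when fewer than two
    bases remain 3' of the cytosine before the chromosome end.  Raises
    ``ValueError`` if the base at the site is not a cytosine on the stated
    strand (a G on the plus strand when ``strand == "-"``).
    """
    seq = genome[chrom]
    if isinstance(seq, (bytes, bytearray)):
        seq = seq.decode()
    seq = str(seq)
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    base = seq[pos].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base}, not C")
        if pos + 2 >= len(seq):
            return None
        nxt1, nxt2 = seq[pos + 1].upper(), seq[pos + 2].upper()
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {base}, not C (G on plus)")
        if pos - 2 < 0:
            return None
        nxt1 = seq[pos - 1].upper().translate(_COMPLEMENT)
        nxt2 = seq[pos - 2].upper().translate(_COMPLEMENT)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt1 not in "ACGT" or nxt2 not in "ACGT":
        return None
    if nxt1 == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def classify_all_cytosines(seq: str, chrom: str = "chr1") -> pd.DataFrame:
    """Vectorised context classification of every cytosine on both strands.

    Returns a frame with columns ``chrom``, ``pos`` (0-based), ``strand``,
    ``context``, sorted by position then strand.  Sites whose context is
    undefined (too close to the sequence end, or an ambiguous base in the
    triplet) are omitted.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = len(arr)
    frames = []

    # plus strand: C at i, context bases at i+1, i+2
    idx = np.flatnonzero(arr == b"C")
    idx = idx[idx + 2 < n]
    if idx.size:
        b1, b2 = arr[idx + 1], arr[idx + 2]
        ok = np.isin(b1, (b"A", b"C", b"G", b"T")) & np.isin(b2, (b"A", b"C", b"G", b"T"))
        idx, b1, b2 = idx[ok], b1[ok], b2[ok]
        ctx = np.where(b1 == b"G", "CG", np.where(b2 == b"G", "CHG", "CHH"))
        frames.append(pd.DataFrame({"pos": idx, "strand": "+", "context": ctx}))

    # minus strand: C is a G on plus at i; 3' bases are complements of i-1, i-2
    idx = np.flatnonzero(arr == b"G")
    idx = idx[idx - 2 >= 0]
    if idx.size:
        b1, b2 = arr[idx - 1], arr[idx - 2]
        ok = np.isin(b1, (b"A", b"C", b"G", b"T")) & np.isin(b2, (b"A", b"C", b"G", b"T"))
        idx, b1, b2 = idx[ok], b1[ok], b2[ok]
        # complement(b)==G  <=>  b==C
        ctx = np.where(b1 == b"C", "CG", np.where(b2 == b"C", "CHG", "CHH"))
        frames.append(pd.DataFrame({"pos": idx, "strand": "-", "context": ctx}))

    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "chrom", chrom)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def site_level(meth_depth: int, total_depth: int) -> float:
    """Methylation level of one site: meth_depth / total_depth.

    Undefined (ValueError) at zero total depth; such sites carry no
    observation and are excluded from averages upstream.
    """
    if total_depth <= 0:
        raise ValueError("site level undefined at total_depth == 0")
    if not 0 <= meth_depth <= total_depth:
        raise ValueError(f"meth_depth {meth_depth} outside [0, {total_depth}]")
    return meth_depth / total_depth


def read_calls(path) -> pd.DataFrame:
    """Read a call table TSV (columns chrom pos strand context meth_depth total_depth)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "pos": np.int64, "strand": str,
                            "context": str, "meth_depth": np.int64,
                            "total_depth": np.int64})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table {path} missing columns: {missing}")
    return df


def write_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def merge_cpg(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse each CpG dyad's two strands into one plus-strand record.

    A minus-strand CG at position p pairs with the plus-strand CG at p-1
    (1-based); their depths are summed.  Off by default throughout the
    package — the two strands are kept separate unless requested.  Non-CG
    rows pass through unchanged.
    """
    cg = calls[calls["context"] == "CG"].copy()
    rest = calls[calls["context"] != "CG"]
    cg["dyad"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    g = cg.groupby(["chrom", "dyad"], observed=True).agg(
        meth_depth=("meth_depth", "sum"), total_depth=("total_depth", "sum")
    ).reset_index().rename(columns={"dyad": "pos"})
    g["strand"] = "+"
    g["context"] = "CG"
    out = pd.concat([g[CALL_COLUMNS], rest[CALL_COLUMNS]], ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def genome_summary(calls: pd.DataFrame, scope: str = "genome") -> pd.DataFrame:
    """Depth-weighted methylation level per context, genome-wide or per chromosome.

    Level = sum(meth_depth) / sum(total_depth) over all covered sites of the
    context within the scope unit.  A context absent from a scope unit gets a
    row with a missing level and zero site count.
    """
    if scope not in ("genome", "chromosome"):
        raise ValueError(f"scope must be 'genome' or 'chromosome', got {scope!r}")
    calls = calls[calls["total_depth"] > 0]
    keys = ["context"] if scope == "genome" else ["chrom", "context"]
    g = calls.groupby(keys, observed=True).agg(
        meth_depth=("meth_depth", "sum"),
        total_depth=("total_depth", "sum"),
        n_sites=("pos", "size"),
    ).reset_index()
    g["level"] = g["meth_depth"] / g["total_depth"]
    # emit rows for missing contexts
    if scope == "genome":
        full = pd.DataFrame({"context": list(CONTEXTS)})
    else:
        chroms = sorted(calls["chrom"].unique()) if len(calls) else []
        full = pd.DataFrame([(c, x) for c in chroms for x in CONTEXTS],
                            columns=["chrom", "context"])
    out = full.merge(g, on=keys, how="left")
    out["n_sites"] = out["n_sites"].fillna(0).astype(int)
    return out


def window_levels(calls: pd.DataFrame, window: int = 2000) -> pd.DataFrame:
    """Pooled levels in non-overlapping tiling windows, per context.

    Windows with no covered eligible site are omitted.  Output columns:
    chrom, start, end (1-based inclusive), context, n_sites, level.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    calls = calls[calls["total_depth"] > 0].copy()
    calls["win"] = (calls["pos"] - 1) // window
    g = calls.groupby(["chrom", "win", "context"], observed=True).agg(
        meth_depth=("meth_depth", "sum"),
        total_depth=("total_depth", "sum"),
        n_sites=("pos", "size"),
    ).reset_index()
    g["level"] = g["meth_depth"] / g["total_depth"]
    g["start"] = g["win"] * window + 1
    g["end"] = (g["win"] + 1) * window
    return g[["chrom", "start", "end", "context", "n_sites",
              "meth_depth", "total_depth", "level"]]


def metagene_profile(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 2000,
    bin_width: int = 100,
    body_bins: int = 20,
    body_mode: str = "proportional",
) -> pd.DataFrame:
    """Average methylation profile over features with 2-kb flanks in 100-bp bins.

    Flanks are binned in literal ``bin_width`` steps (``flank // bin_width``
    bins each side).  Bodies are length-normalised into ``body_bins``
    proportional bins by default (``body_mode="fixed100"`` instead tiles the
    body in literal 100-bp bins, using each feature's own bin count).  Minus
    strand features are reversed so bin 1 is always the 5' end.  Within a bin
    the per-feature value is the unweighted mean of site levels; the profile
    value is the mean of per-feature bin means over features that have at
    least one covered site in the bin.

    ``features`` needs columns chrom, start, end (1-based inclusive), strand.
    Returns columns: context, region (upstream/body/downstream), bin (1-based
    within region), mean_level, n_sites, n_features.
    """
    if body_mode not in ("proportional", "fixed100"):
        raise ValueError(f"unknown body_mode {body_mode!r}")
    n_flank_bins = flank // bin_width
    calls = calls[calls["total_depth"] > 0].copy()
    calls["level"] = calls["meth_depth"] / calls["total_depth"]

    rows = []  # (context, region, bin, level-sum, n_sites) per feature-bin
    for feat in features.itertuples(index=False):
        fchrom, fstart, fend, fstrand = feat.chrom, int(feat.start), int(feat.end), feat.strand
        flen = fend - fstart + 1
        sub = calls[(calls["chrom"] == fchrom)
                    & (calls["pos"] >= fstart - flank)
                    & (calls["pos"] <= fend + flank)]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        if fstrand == "-":
            # mirror coordinates so the 5' flank comes first
            rel = fend - pos
        else:
            rel = pos - fstart
        # rel < 0: upstream flank; 0 <= rel < flen: body; rel >= flen: downstream
        region = np.where(rel < 0, "upstream", np.where(rel < flen, "body", "downstream"))
        binno = np.empty(len(rel), dtype=int)
        up = rel < 0
        binno[up] = n_flank_bins + 1 + (rel[up] // bin_width)  # rel=-1 -> last upstream bin
        body = (~up) & (rel < flen)
        if body_mode == "proportional":
            nb = min(body_bins, flen)  # short feature: fewer bins, flagged via n < body_bins
            binno[body] = np.minimum((rel[body] * nb) // flen, nb - 1) + 1
        else:
            binno[body] = rel[body] // bin_width + 1
        down = rel >= flen
        binno[down] = (rel[down] - flen) // bin_width + 1
        df = pd.DataFrame({"context": sub["context"].to_numpy(), "region": region,
                           "bin": binno, "level": sub["level"].to_numpy()})
        df = df[(df["region"] != "upstream") | ((df["bin"] >= 1) & (df["bin"] <= n_flank_bins))]
        df = df[(df["region"] != "downstream") | (df["bin"] <= n_flank_bins)]
        g = df.groupby(["context", "region", "bin"], observed=True)["level"].agg(["mean", "size"])
        for (ctx, reg, b), row in g.iterrows():
            rows.append((ctx, reg, int(b), row["mean"], int(row["size"])))

    if not rows:
        return pd.DataFrame(columns=["context", "region", "bin", "mean_level",
                                     "n_sites", "n_features"])
    per_feat = pd.DataFrame(rows, columns=["context", "region", "bin", "feat_mean", "n"])
    out = per_feat.groupby(["context", "region", "bin"], observed=True).agg(
        mean_level=("feat_mean", "mean"),
        n_sites=("n", "sum"),
        n_features=("feat_mean", "size"),
    ).reset_index()
    order = pd.CategoricalDtype(["upstream", "body", "downstream"], ordered=True)
    out["region"] = out["region"].astype(order)
    return out.sort_values(["context", "region", "bin"]).reset_index(drop=True)
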