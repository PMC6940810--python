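"""Stage-success ratios of the cloning (SCNT) embryo production program.

Each batch of oocytes progresses mature -> clone (nuclear transfer) ->
fusion -> cleavage, each stage recording failure and success counts; the
success ratio is 100 * success / (failure + success), rounded half-up to
two decimals.  Overall ratios per year and stage are computed on summed
counts, never by averaging per-batch ratios.  The packaged fixture tables
transcribe a published breeding program's per-batch counts (20 batches over
two years) and birth statistics; the known cross-stage bookkeeping
inconsistency in the source (2015 cleavage failures+successes, 501, differs
from the 519 fusion successes) is carried as-is.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

STAGES = ["mature", "clone", "fusion", "cleavage"]


def load_embryo_batches() -> pd.DataFrame:
    """Per-batch per-stage failure/success counts (fixture).

    Columns: year, batch, stage, failure, success, c2, c4, c8plus (cleavage
    only; success = c2 + c4 + c8plus), printed_ratio (the source's printed
    percentage, for cross-checking).
    """
    with resources.files("caprameth.data").joinpath("embryo_batches.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"year": str}, na_values=["NA"])
    return df


def load_birth_stats() -> pd.DataFrame:
    """Per-group birth statistics (fixture; transcription only)."""
    with resources.files("caprameth.data").joinpath("birth_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"year": str}, na_values=["NA"])


def success_ratio(failure: int, success: int) -> float:
    """100 * success / (failure + success), half-up rounded to 2 decimals.

    Undefined (NaN) when both counts are zero.
    """
    if failure < 0 or success < 0:
        raise ValueError("counts must be non-negative")
    total = failure + success
    if total == 0:
        return math.nan
    ratio = Decimal(100) * Decimal(success) / Decimal(total)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_table(batches: pd.DataFrame) -> pd.DataFrame:
    """Per-batch ratios plus per-(year, stage) overall rows on summed counts.

    Overall rows carry batch = 0.
    """
    rows = []
    for b in batches.itertuples(index=False):
        rows.append((b.year, int(b.batch), b.stage, int(b.failure), int(b.success),
                     success_ratio(int(b.failure), int(b.success))))
    for (year, stage), sub in batches.groupby(["year", "stage"], observed=True):
        f, s = int(sub["failure"].sum()), int(sub["success"].sum())
        rows.append((year, 0, stage, f, s, success_ratio(f, s)))
    out = pd.DataFrame(rows, columns=["year", "batch", "stage",
                                      "failure", "success", "ratio"])
    stage_order = pd.CategoricalDtype(STAGES, ordered=True)
    out["stage"] = out["stage"].astype(stage_order)
    return out.sort_values(["year", "batch", "stage"],
                           key=lambda c: c.replace(0, 99) if c.name == "batch" else c
                           ).reset_index(drop=True)


def check_cleavage_consistency(batches: pd.DataFrame) -> pd.DataFrame:
    """Verify cleavage success = 2C + 4C + >=8C per batch; return violations."""
    clv = batches[batches["stage"] == "cleavage"].copy()
    parts = clv[["c2", "c4", "c8plus"]].fillna(0).astype(int).sum(axis=1)
    bad = clv[parts != clv["success"].astype(int)]
    return bad[["year", "batch", "failure", "success", "c2", "c4", "c8plus"]]
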