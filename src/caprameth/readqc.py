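"""Raw-read filtering: drop reads with too many unknown or low-quality bases.

Two rules, both strict inequalities, applied in order:

1. drop a read whose fraction of unknown nucleotides exceeds ``max_n_frac``
   (default 10%); any character other than A/C/G/T, case-insensitively,
   counts as unknown;
2. drop a read whose fraction of bases at or below ``q_threshold``
   (default Q20, i.e. Q <= 20 counts as low quality) exceeds
   ``max_lowq_frac`` (default 40%).

Surviving reads keep their input order.  Paired-end linkage (drop both
mates when either fails) is available via :func:`filter_read_pairs`; the
default semantics are per-read.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

_VALID = frozenset("ACGTacgt")


@dataclasses.dataclass
class ReadQCReport:
    total: int = 0
    kept: int = 0
    dropped_n: int = 0
    dropped_q: int = 0

    def __post_init__(self):
        if self.kept + self.dropped_n + self.dropped_q != self.total:
            raise ValueError("QC report counts do not add up")


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fastq(path):
    """Yield (read_id, seq, qualities) tuples; hard error on malformed records."""
    from Bio import SeqIO

    idx = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]
                idx += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {idx} in {path}: {exc}") from exc


def classify_read(seq: str, quals, max_n_frac: float = 0.10,
                  q_threshold: int = 20, max_lowq_frac: float = 0.40) -> str:
    """Fate of one read: 'pass', 'n_fail' (rule 1, checked first) or 'q_fail'."""
    n = len(seq)
    if n == 0:
        return "pass"
    n_unknown = sum(1 for b in seq if b not in _VALID)
    if n_unknown / n > max_n_frac:
        return "n_fail"
    n_lowq = sum(1 for q in quals if q <= q_threshold)
    if n_lowq / n > max_lowq_frac:
        return "q_fail"
    return "pass"


def filter_reads(in_path, out_path=None, max_n_frac: float = 0.10,
                 q_threshold: int = 20, max_lowq_frac: float = 0.40) -> ReadQCReport:
    """Filter a FASTQ file (gzip ok); write survivors and return the report."""
    total = kept = dropped_n = dropped_q = 0
    out = _open_text(out_path, "wt") if out_path is not None else None
    try:
        if Path(str(in_path)).stat().st_size == 0:
            return ReadQCReport()
        for rid, seq, quals in _iter_fastq(in_path):
            total += 1
            fate = classify_read(seq, quals, max_n_frac, q_threshold, max_lowq_frac)
            if fate == "n_fail":
                dropped_n += 1
            elif fate == "q_fail":
                dropped_q += 1
            else:
                kept += 1
                if out is not None:
                    qual = "".join(chr(q + 33) for q in quals)
                    out.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    finally:
        if out is not None:
            out.close()
    return ReadQCReport(total=total, kept=kept, dropped_n=dropped_n, dropped_q=dropped_q)


def filter_read_pairs(in1, in2, out1, out2, drop_if_either: bool = True,
                      max_n_frac: float = 0.10, q_threshold: int = 20,
                      max_lowq_frac: float = 0.40) -> tuple[ReadQCReport, ReadQCReport]:
    """Paired filtering; with ``drop_if_either`` a failing mate drops the pair.

    Each mate's report counts its own fate; a read dropped only because its
    mate failed is counted under the mate's failure mode of that mate's
    report but stays 'kept' in its own unless it also fails — in
    ``drop_if_either`` mode the pair simply is not written.
    """
    r1 = list(_iter_fastq(in1))
    r2 = list(_iter_fastq(in2))
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in length: {len(r1)} vs {len(r2)}")
    rep1 = dict(total=0, kept=0, dropped_n=0, dropped_q=0)
    rep2 = dict(total=0, kept=0, dropped_n=0, dropped_q=0)
    with _open_text(out1, "wt") as o1, _open_text(out2, "wt") as o2:
        for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
            f1 = classify_read(s1, q1, max_n_frac, q_threshold, max_lowq_frac)
            f2 = classify_read(s2, q2, max_n_frac, q_threshold, max_lowq_frac)
            for rep, fate in ((rep1, f1), (rep2, f2)):
                rep["total"] += 1
                if fate == "n_fail":
                    rep["dropped_n"] += 1
                elif fate == "q_fail":
                    rep["dropped_q"] += 1
                else:
                    rep["kept"] += 1
            write = (f1 == "pass" and f2 == "pass") if drop_if_either \
                else True  # per-read mode writes each passing mate below
            if drop_if_either:
                if write:
                    o1.write(f"@{id1}\n{s1}\n+\n{''.join(chr(q + 33) for q in q1)}\n")
                    o2.write(f"@{id2}\n{s2}\n+\n{''.join(chr(q + 33) for q in q2)}\n")
            else:
                if f1 == "pass":
                    o1.write(f"@{id1}\n{s1}\n+\n{''.join(chr(q + 33) for q in q1)}\n")
                if f2 == "pass":
                    o2.write(f"@{id2}\n{s2}\n+\n{''.join(chr(q + 33) for q in q2)}\n")
    return (ReadQCReport(**rep1), ReadQCReport(**rep2))
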