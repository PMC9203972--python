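"""3' adapter trimming, length-window filtering, and read collapsing.

Small-RNA libraries are sequenced longer than the insert, so every read is
expected to run into the 3' adapter; the insert is whatever lies upstream of
the first adapter occurrence. Inserts shorter than 8 nt are discarded — below
that length a sequence no longer identifies a genomic locus even approximately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io import ReadRecord

__all__ = [
    "TrimStatus",
    "TrimResult",
    "UniqueSeqCount",
    "trim_adapter",
    "trim_library",
    "collapse_reads",
    "window_filter",
    "MIN_INSERT_LEN",
    "MAX_ANALYSIS_LEN",
]

MIN_INSERT_LEN = 8
MAX_ANALYSIS_LEN = 30


class TrimStatus(str, Enum):
    TRIMMED = "trimmed"
    UNTRIMMED = "untrimmed"  # no adapter found; insert = whole read, kept but flagged
    TOO_SHORT = "too_short"  # insert < 8 nt, discarded
    CONTAINS_N = "contains_n"  # ambiguous base in insert, discarded


@dataclass(frozen=True)
class TrimResult:
    insert: str | None
    status: TrimStatus

    @property
    def kept(self) -> bool:
        return self.insert is not None


@dataclass(frozen=True)
class UniqueSeqCount:
    """A collapsed unique sequence and its read multiplicity."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 6) -> TrimResult:
    """Locate the 3' adapter in a read and return the upstream insert.

    Search order: the leftmost occurrence of the *full* adapter anywhere in
    the read wins; failing that, the longest adapter *prefix* (>= min_overlap
    nt, exact match) flush with the read's 3' end. Reads with no adapter
    evidence are kept whole and flagged ``untrimmed``. Inserts shorter than
    8 nt or containing N are discarded.
    """
    adapter = adapter.upper()
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter ({len(adapter)} nt) shorter than min_overlap ({min_overlap})"
        )
    seq = read.seq.upper()

    pos = seq.find(adapter)
    status = TrimStatus.TRIMMED
    if pos < 0:
        # partial adapter at the read end: longest prefix match wins (leftmost cut)
        pos = -1
        max_len = min(len(adapter) - 1, len(seq))
        for k in range(max_len, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                pos = len(seq) - k
                break
        if pos < 0:
            pos = len(seq)
            status = TrimStatus.UNTRIMMED

    insert = seq[:pos]
    if len(insert) < MIN_INSERT_LEN:
        return TrimResult(None, TrimStatus.TOO_SHORT)
    if "N" in insert:
        return TrimResult(None, TrimStatus.CONTAINS_N)
    return TrimResult(insert, status)


def trim_library(
    reads: Iterable[ReadRecord], adapter: str, min_overlap: int = 6
) -> tuple[list[str], Counter]:
    """Trim every read; return kept inserts plus a status tally."""
    inserts: list[str] = []
    tally: Counter = Counter()
    for read in reads:
        res = trim_adapter(read, adapter, min_overlap)
        tally[res.status] += 1
        if res.kept:
            inserts.append(res.insert)  # type: ignore[arg-type]
    return inserts, tally


def collapse_reads(inserts: Iterable[str]) -> list[UniqueSeqCount]:
    """Collapse inserts to unique sequences with counts (case-insensitive).

    Counts sum to the number of input inserts; output is ordered by
    descending count, ties by sequence, so it is deterministic.
    """
    counter = Counter(s.upper() for s in inserts)
    return [
        UniqueSeqCount(seq, n)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def window_filter(
    seqs: Sequence[UniqueSeqCount],
    lo: int = MIN_INSERT_LEN,
    hi: int = MAX_ANALYSIS_LEN,
) -> list[UniqueSeqCount]:
    """Retain unique sequences whose length is in [lo, hi]; counts untouched."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) > hi ({hi})")
    return [u for u in seqs if lo <= len(u.seq) <= hi]
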