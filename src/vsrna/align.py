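"""Exhaustive exact-match placement of 8-30 nt sequences on both genome strands.

At these lengths a single mismatch is a different molecule, and multimapping
is the norm rather than the exception, so the aligner enumerates *all* exact
placements: an 8-mer seed index (8 = the minimum insert length) over both
strands, with plain string-comparison extension. No mismatches, gaps, or
mapping qualities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .trim import UniqueSeqCount

__all__ = ["Hit", "GenomeIndex", "build_index", "align_seq", "map_library", "revcomp"]

SEED_LEN = 8
MAX_QUERY_LEN = 30

_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


@dataclass(frozen=True, order=True)
class Hit:
    """One exact placement: 0-based half-open genomic interval plus strand.

    For strand ``-`` the query equals the reverse complement of the genomic
    substring; coordinates always refer to the forward (top) strand.
    """

    contig: str
    start: int
    end: int
    strand: str
    query_seq: str = field(compare=False, default="")


@dataclass
class GenomeIndex:
    """Seed index: every 8-mer occurrence on either strand of every contig.

    ``seed_index[kmer]`` lists ``(contig, offset, strand)`` where ``offset``
    is the forward-strand start of the 8-base window; a ``-`` entry means
    the 8-mer is read off the reverse strand of that window.
    """

    contigs: dict[str, str]
    seed_index: dict[str, list[tuple[str, int, str]]]


def build_index(genome: dict[str, str]) -> GenomeIndex:
    """Index all 8-mers of all contigs, both strands.

    Raises ValueError on non-ACGT characters (contig and position reported);
    contigs shorter than the seed are accepted but unhittable.
    """
    idx: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    contigs: dict[str, str] = {}
    for name in sorted(genome):
        seq = genome[name].upper()
        bad = next((i for i, c in enumerate(seq) if c not in "ACGT"), None)
        if bad is not None:
            raise ValueError(
                f"contig {name!r} position {bad}: non-ACGT character {seq[bad]!r}"
            )
        contigs[name] = seq
        for off in range(len(seq) - SEED_LEN + 1):
            kmer = seq[off : off + SEED_LEN]
            idx[kmer].append((name, off, "+"))
            idx[revcomp(kmer)].append((name, off, "-"))
    return GenomeIndex(contigs=contigs, seed_index=dict(idx))


def align_seq(seq: str, index: GenomeIndex) -> list[Hit]:
    """All exact placements of ``seq`` on both strands, deterministically ordered.

    Seeds on the query's first 8-mer and verifies the full window by string
    comparison. Order is (contig, start, strand). Raises ValueError for
    queries outside 8-30 nt.
    """
    seq = seq.upper()
    n = len(seq)
    if not SEED_LEN <= n <= MAX_QUERY_LEN:
        raise ValueError(f"query length {n} outside [{SEED_LEN}, {MAX_QUERY_LEN}]")
    hits: set[Hit] = set()
    for contig, off, strand in index.seed_index.get(seq[:SEED_LEN], ()):
        ref = index.contigs[contig]
        if strand == "+":
            start = off
            if start + n <= len(ref) and ref[start : start + n] == seq:
                hits.add(Hit(contig, start, start + n, "+", seq))
        else:
            # query's first 8-mer sits at the *right* edge of the genomic window
            start = off + SEED_LEN - n
            if start >= 0 and revcomp(ref[start : start + n]) == seq:
                hits.add(Hit(contig, start, start + n, "-", seq))
    return sorted(hits, key=lambda h: (h.contig, h.start, h.strand))


def map_library(
    counts: Sequence[UniqueSeqCount], index: GenomeIndex
) -> tuple[dict[str, list[Hit]], set[str], float]:
    """Align every unique sequence; return (hits by seq, unmapped set, mapped fraction).

    The mapped fraction is count-weighted: multiplicity is a property of the
    sequence, so a 1000-copy sequence weighs 1000 reads regardless of how
    many placements it has.
    """
    mapped: dict[str, list[Hit]] = {}
    unmapped: set[str] = set()
    n_mapped = 0
    n_total = 0
    for u in counts:
        n_total += u.count
        hits = align_seq(u.seq, index)
        if hits:
            mapped[u.seq] = hits
            n_mapped += u.count
        else:
            unmapped.add(u.seq)
    frac = n_mapped / n_total if n_total else 0.0
    return mapped, unmapped, frac
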