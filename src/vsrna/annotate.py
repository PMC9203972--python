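"""Biotype assignment and positional tRNA-fragment (tRF) classification.

Each mapped sequence receives exactly ONE biotype. Where placements overlap
several feature classes the structured-RNA-first precedence
tRNA > rRNA > ncRNA > mRNA applies: tRNA and rRNA fragments are called as
such even when the locus also lies inside a transcribed protein-coding
region. A mapped sequence overlapping no feature is "other" (intergenic);
a sequence with no placement at all is "unmapped".

tRFs are classified positionally against the parent tRNA: a fragment whose
biological 5' end sits within 1 nt of the mature tRNA's 5' end is tRF-5,
within 1 nt of the 3' end is tRF-3 (tRF-5 wins if both), anything else is
internal. The D-arm cleavage motif TAGC (and its TAGCT extension) is
reported per fragment together with the distance from motif end to the cut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .align import Hit

__all__ = [
    "Feature",
    "BiotypeCall",
    "TrfRecord",
    "BIOTYPE_PRECEDENCE",
    "classify_seq",
    "classify_trf",
    "motif_context",
    "canonical_biotype",
]

#: resolution order for sequences overlapping multiple feature classes
BIOTYPE_PRECEDENCE = ("tRNA", "rRNA", "ncRNA", "mRNA")

D_ARM_MOTIF = "TAGC"
D_ARM_MOTIF_EXT = "TAGCT"


@dataclass(frozen=True)
class Feature:
    """A genome feature: 0-based half-open interval, strand, biotype, name."""

    contig: str
    start: int
    end: int
    strand: str
    biotype: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name!r}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sense_seq(self, genome: dict[str, str]) -> str:
        from .align import revcomp

        sub = genome[self.contig][self.start : self.end]
        return sub if self.strand == "+" else revcomp(sub)


def canonical_biotype(raw: str) -> str:
    """Map an annotation biotype to the closed vocabulary.

    tRNA, rRNA and mRNA (protein_coding) pass through; every other annotated
    class collapses into the ncRNA bucket.
    """
    if raw in ("tRNA", "rRNA", "mRNA"):
        return raw
    if raw == "protein_coding":
        return "mRNA"
    return "ncRNA"


@dataclass(frozen=True)
class BiotypeCall:
    seq: str
    biotype: str  # tRNA | rRNA | ncRNA | mRNA | other | unmapped
    supporting_hit: Hit | None = None
    family: str | None = None


@dataclass(frozen=True)
class TrfRecord:
    seq: str
    parent_trna: str
    five_prime_offset: int
    trf_class: str  # tRF-5 | tRF-3 | internal
    motif_found: bool = False
    motif: str = D_ARM_MOTIF
    motif_end_to_cut_distance: int | None = None
    extended_motif_found: bool = False


def _overlaps(hit: Hit, f: Feature) -> bool:
    return (
        hit.contig == f.contig
        and hit.strand == f.strand
        and hit.start < f.end
        and hit.end > f.start
    )


def _bio5(hit: Hit) -> int:
    """Genomic coordinate of the hit's biological 5' end (0-based)."""
    return hit.start if hit.strand == "+" else hit.end - 1


def classify_seq(
    seq: str, hits: Sequence[Hit], features: Sequence[Feature]
) -> BiotypeCall:
    """Resolve a sequence's placements against the annotation to one biotype.

    Overlap means >= 1 shared base on the matching strand. Among candidate
    features, those containing the fragment's biological 5' end are preferred
    (the 5' end defines a tRF's identity); the winner is picked by biotype
    precedence, then leftmost coordinate, then name.
    """
    if not hits:
        return BiotypeCall(seq, "unmapped")

    candidates: list[tuple[Feature, Hit, bool]] = []
    for hit in hits:
        for f in features:
            if _overlaps(hit, f):
                contains5 = f.start <= _bio5(hit) < f.end
                candidates.append((f, hit, contains5))
    if not candidates:
        return BiotypeCall(seq, "other", supporting_hit=hits[0])

    if any(c5 for _, _, c5 in candidates):
        candidates = [c for c in candidates if c[2]]

    def rank(c: tuple[Feature, Hit, bool]):
        f = c[0]
        bt = canonical_biotype(f.biotype)
        return (BIOTYPE_PRECEDENCE.index(bt), f.start, f.name)

    f, hit, _ = min(candidates, key=rank)
    return BiotypeCall(
        seq, canonical_biotype(f.biotype), supporting_hit=hit, family=f.name
    )


def classify_trf(hit: Hit, trna: Feature, tolerance: int = 1) -> TrfRecord:
    """Classify a tRNA-overlapping fragment by its position on the mature tRNA.

    Offsets are strand-aware distances along the tRNA's own 5'->3' axis, so
    a minus-strand tRNA's biological 5' end is its genomic right edge.
    Raises ValueError if the hit does not overlap the tRNA.
    """
    if not _overlaps(hit, trna):
        raise ValueError(
            f"hit {hit.contig}:{hit.start}-{hit.end}({hit.strand}) does not "
            f"overlap tRNA {trna.name!r}"
        )
    if trna.strand == "+":
        five_off = hit.start - trna.start
        three_off = trna.end - hit.end
    else:
        five_off = trna.end - hit.end
        three_off = hit.start - trna.start

    if abs(five_off) <= tolerance:
        cls = "tRF-5"
    elif abs(three_off) <= tolerance:
        cls = "tRF-3"
    else:
        cls = "internal"
    return TrfRecord(
        seq=hit.query_seq, parent_trna=trna.name, five_prime_offset=five_off, trf_class=cls
    )


def motif_context(trf: TrfRecord, fragment_seq: str) -> TrfRecord:
    """Annotate a tRF-5 with the D-arm cleavage-motif context.

    ``motif_end_to_cut_distance`` is the number of nucleotides between the
    last TAGC occurrence's end and the fragment's 3' cut site: 0 means the
    fragment ends flush with the motif, 2 is the canonical 13-nt product of
    a motif at positions 8-11.
    """
    if trf.trf_class != "tRF-5":
        raise ValueError("motif context is defined for tRF-5 fragments only")
    fragment_seq = fragment_seq.upper()
    pos = fragment_seq.rfind(D_ARM_MOTIF)
    if pos < 0:
        return replace(trf, seq=fragment_seq, motif_found=False,
                       motif_end_to_cut_distance=None, extended_motif_found=False)
    end_1based = pos + len(D_ARM_MOTIF)
    return replace(
        trf,
        seq=fragment_seq,
        motif_found=True,
        motif_end_to_cut_distance=len(fragment_seq) - end_1based,
        extended_motif_found=D_ARM_MOTIF_EXT in fragment_seq,
    )
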