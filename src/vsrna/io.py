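"""File-format boundary: FASTA/FASTQ, GFF3, TSV count tables, SAM.

All genomic coordinates are 0-based half-open in memory; GFF3 (1-based,
inclusive) is converted at this boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # io <- annotate <- align <- trim <- io would cycle at runtime
    from .annotate import Feature

__all__ = [
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "write_gff3",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_sam",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence over {A,C,G,T,N}, optional quality."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-line) FASTA file into {name: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# --- GFF3 ---------------------------------------------------------------

_GFF_COLS = 9


def read_gff3(path: str | Path) -> list[Feature]:
    """Parse a GFF3 file into Features (strict: 9 tab-separated columns).

    Recognized attributes: ``gene_biotype`` or ``biotype`` for the RNA class,
    ``Name`` (falling back to ``ID``) for the feature/family name.
    """
    from .annotate import Feature

    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, _type, start1, end1, _score, strand, _phase, attrs = cols
            attr = {}
            for kv in attrs.split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k.strip()] = v.strip()
            biotype = attr.get("gene_biotype") or attr.get("biotype")
            if biotype is None:
                raise ValueError(f"{path}:{lineno}: missing gene_biotype/biotype attribute")
            name = attr.get("Name") or attr.get("ID") or f"feature_{lineno}"
            feats.append(
                Feature(
                    contig=contig,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    biotype=biotype,
                    name=name,
                )
            )
    return feats


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "vsrna") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features, 1):
            attrs = f"ID=feat{i};Name={f.name};gene_biotype={f.biotype}"
            fh.write(
                f"{f.contig}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# --- collapsed-count TSV ------------------------------------------------


def write_counts_tsv(counts: "pd.DataFrame | list", path: str | Path) -> None:
    """Write unique-sequence counts as TSV with columns rank, count, sequence.

    Accepts a DataFrame with ``seq``/``count`` columns or a list of objects
    with those attributes; rows are ranked by descending count, ties broken
    by sequence.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame([(c.seq, c.count) for c in counts], columns=["seq", "count"])
    df = counts.sort_values(["count", "seq"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    out = pd.DataFrame(
        {"rank": range(1, len(df) + 1), "count": df["count"], "sequence": df["seq"]}
    )
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"seq": df["sequence"].str.upper(), "count": df["count"]})


# --- SAM ----------------------------------------------------------------


def write_sam(
    hits_by_seq: dict[str, list],
    contigs: dict[str, str],
    path: str | Path | TextIO,
) -> None:
    """Write one SAM alignment line per placement (NH = number of placements).

    Minus-strand hits carry flag 16 and the reverse-complemented sequence in
    SEQ, per SAM convention. Exact matches only, so CIGAR is ``<len>M``.
    """
    from .align import revcomp  # local import to avoid cycle

    fh: TextIO
    close = False
    if isinstance(fh_or := path, (str, Path)):
        fh = open(fh_or, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for seq, hits in hits_by_seq.items():
            nh = len(hits)
            for h in hits:
                flag = 0 if h.strand == "+" else 16
                sam_seq = seq if h.strand == "+" else revcomp(seq)
                fh.write(
                    f"{seq}\t{flag}\t{h.contig}\t{h.start + 1}\t255\t"
                    f"{len(seq)}M\t*\t0\t0\t{sam_seq}\t*\tNH:i:{nh}\n"
                )
    finally:
        if close:
            fh.close()
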