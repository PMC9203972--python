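"""Bundled worked-example data: published top-20 abundance tables.

The package ships the top-20 most abundant adapter-trimmed read sequences
(8-30 nt) observed in an E. coli K-12 culture and in the outer membrane
vesicles (OMVs) it secreted, with their read counts and annotated origins.
These two small tables are the package's standing worked example: they
carry the canonical 13-nt tRF-5 species (e.g. AGGCTTGTAGCTC from tRNA-Ile)
and reproduce the selective-loading fold-enrichments of Ile- and Ala-tRFs
in OMVs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quantify import AnnotatedCountTable

__all__ = ["load_top20", "TRF_FAMILIES"]

_FILES = {
    "cell": "ecoli_cell_top20.tsv",
    "omv": "ecoli_omv_top20.tsv",
}

#: tRF families annotated in the bundled tables
TRF_FAMILIES = ("tRNA-Ile", "tRNA-Ala", "tRNA-Pro")


def load_top20(which: str, as_table: bool = False) -> "pd.DataFrame | AnnotatedCountTable":
    """Load a bundled top-20 table ('cell' or 'omv').

    Returns a DataFrame with columns rank, count, seq, family, length (family
    is the annotated origin, e.g. 'tRNA-Ile' or 'mRNA fragment'). With
    ``as_table=True``, wraps it as an AnnotatedCountTable whose biotype is
    derived from the origin string; note the CPM denominator is then the
    top-20 sum, not the (unpublished) full library total.
    """
    try:
        fname = _FILES[which]
    except KeyError:
        raise ValueError(f"which must be one of {sorted(_FILES)}, got {which!r}")
    with resources.files("vsrna.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["length"] = df["seq"].str.len()
    if not as_table:
        return df

    def biotype(origin: str) -> str:
        if origin.startswith("tRNA"):
            return "tRNA"
        if "rRNA" in origin:
            return "rRNA"
        if origin.startswith("mRNA"):
            return "mRNA"
        return "unmapped" if origin == "No hit" else "ncRNA"

    rows = [(r.seq, r.count, biotype(r.family), r.family) for r in df.itertuples()]
    return AnnotatedCountTable.from_rows(rows)
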