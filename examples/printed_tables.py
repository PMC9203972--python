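"""Worked example: tRF-family enrichment from the bundled top-20 tables.

Loads the shipped E. coli cell and OMV top-20 abundance tables and
recomputes the selective-loading statements: fold-enrichment of the Ile-
and Ala-tRF families in OMVs relative to cells, their relative abundance
within OMVs, and the modal tRF length.
"""

from vsrna import family_enrichment, load_top20, round_half_away
from vsrna.quantify import family_abundance

cell = load_top20("cell")
omv = load_top20("omv")

for family in ("tRNA-Ile", "tRNA-Ala"):
    raw, rounded = family_enrichment(cell, omv, family)
    print(f"{family}: {raw:.2f}-fold enriched in OMVs (rounded: {rounded}x)")

ratio = family_abundance(omv, "tRNA-Ile") / family_abundance(omv, "tRNA-Ala")
print(f"within OMVs, Ile-tRF / Ala-tRF abundance: {ratio:.2f} (~{round_half_away(ratio)}x)")

trf = omv[omv["family"].str.startswith("tRNA")]
modal = trf.groupby("length")["count"].sum().idxmax()
print(f"modal length of tRNA-derived reads in the OMV table: {modal} nt")

# A rounded enrichment > 1 means the family is over-represented in vesicles
# relative to the producing cells, i.e. selectively loaded.
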