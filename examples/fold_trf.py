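"""Worked example: secondary structure of the abundant 13-nt tRFs.

Folds the two most abundant tRF species from the bundled tables under the
exact integer pair-energy model and prints their dot-bracket structures.
A "hairpin" shape with >= 2 G-C pairs indicates a thermodynamically stable
stem-loop; "open" means no stable stem exists.
"""

from vsrna import classify_shape, mfe_fold, to_rna

for name, seq in [
    ("Ile-tRF", "AGGCTTGTAGCTC"),
    ("Ala-tRF", "GGGGCTATAGCTC"),
    ("poly-A control", "AAAAAAAAAAAAA"),
]:
    st = mfe_fold(to_rna(seq))
    print(f"{name:15s} {st.seq}")
    print(f"{'':15s} {st.dot_bracket}  energy={st.energy} model units, "
          f"G-C pairs={st.gc_pairs}, shape={classify_shape(st)}")

# Energies are in the bespoke model's integer units (G-C = -3, A-U = -2,
# G-U = -1 per pair), not kcal/mol; more negative = more stable.
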