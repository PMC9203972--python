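# Methods

## Problem setting

Small-RNA sequencing of bacterial cells and their outer membrane vesicles
(OMVs) reveals a population of very small RNAs (vsRNAs, 8–15 nt) that
standard pipelines drop at their ~16-nt cutoff. The analyses this package
implements are the ones that window forces: exact, exhaustive alignment
(multimapping dominates), single-biotype resolution per *sequence* rather
than per placement, positional tRF classification, abundance comparison
between compartments, and structure characterization small enough to be
solved exactly.

## Pipeline model and assumptions

A library is a multiset of reads, each an RNA fragment followed by the 3′
adapter, sequenced for a fixed number of cycles (default 51). Stages:

1. **Trimming.** The leftmost occurrence of the full adapter defines the
   insert; failing that, the longest adapter *prefix* (≥ `min_overlap` = 6 nt,
   exact match) flush with the read's 3′ end. Matching is exact: no error
   model is assumed, which keeps the stage oracle-testable. Inserts < 8 nt or
   containing N are discarded; reads with no adapter evidence are kept whole
   and flagged `untrimmed` (they fall out of the 8–30-nt window anyway for
   full-length reads). Sequences are held in the DNA alphabet internally; the
   structure module converts to RNA on entry.
2. **Collapsing.** Unique sequences with counts; count conservation (sum of
   counts = retained inserts) is asserted by tests. Abundance is a property
   of the sequence, not of a placement — multimapped sequences are never
   fractionally split.
3. **Alignment.** 8-mer seed (8 = minimum insert), both strands, plain string
   extension, all placements returned in (contig, start, strand) order.
   Equivalence with a naive double-strand sliding-window scan is a standing
   property test. No mismatches or gaps, by design: at ≤ 30 nt a mismatch is
   a different molecule, and published mapping rates for real libraries
   depend on a specific aligner's tolerance settings, so they are not
   reproduction targets here.
4. **Annotation.** Overlap = ≥ 1 shared base on the matching strand. Among
   overlapping features, ones containing the fragment's biological 5′ end are
   preferred (the 5′ end defines tRF identity); the winner is chosen by
   precedence `tRNA > rRNA > ncRNA > mRNA`, then leftmost start, then name.
   The `ncRNA` bucket absorbs every annotated biotype that is not tRNA, rRNA
   or protein-coding. The precedence rule is this package's choice: category
   definitions of this kind never state a multi-overlap resolution, and
   structured-RNA-first matches how tRF/rRNA fragments are reported in
   practice. Whether a historical pipeline resolved multimappers per
   placement or per sequence is likewise unstated; per-sequence is our
   documented behavior.
5. **tRF classes.** `tRF-5` when |5′ offset| ≤ 1 nt (tolerance for ragged
   processing; flush alignment is the canonical case), `tRF-3` within 1 nt of
   the 3′ terminus (tRF-5 wins if both), else `internal`. The D-arm motif
   `TAGC` is reported with the distance from its last occurrence's end to the
   cut site (2 for the canonical 13-nt product of a motif at positions 8–11),
   plus the extended `TAGCT` form. tRNA halves (31–40 nt) are outside the
   30-nt ceiling and out of scope, as is any modification-aware analysis
   (a pseudouridine at position 13 is invisible to sequence).
6. **Quantification.** CPM = count / library total × 10⁶. "TPM"/"RPM" labels
   in this field's small-RNA literature refer to this same tag-count
   normalization; gene-length-normalized TPM would be meaningless for unique
   short sequences, so one quantity is implemented under all labels.
   Medium subtraction removes *exact* sequences observed in the sterile-medium
   control and renormalizes on the new total — identity, not alignment,
   because a contaminant is defined by having been sequenced from the medium.
   Family fold-enrichment uses raw counts when comparing printed top-N
   extracts and CPM when comparing full libraries; rounding is
   half-away-from-zero, the rule consistent with the published 9×/18×/4×
   statements (their raw ratios: 9.15, 17.86, 3.87). The published "7×"
   Ile/Ala cell-side figure has raw ratio 7.55 and rounds to 8 under the same
   rule; no single rounding rule reproduces all four, so that one is reported
   raw and not targeted.

## Structure model

Nested base pairs from {G-C, A-U, G-U}, pair energies −3/−2/−1 integer model
units, minimum hairpin loop 3, no dangles or loop penalties — the smallest
model that preserves the qualitative claims at stake (G-C-driven stem
stability; hairpin vs unstructured). Published kcal/mol values from
Turner-parameter folders are *not* comparable and are not targets; the
model's virtue is that ≤ 30-nt sequences admit exhaustive enumeration, so the
DP fold is verified against the full structure list in the test suite and in
the acceptance script. Ties at minimum energy resolve to (fewest pairs, then
lexicographically smallest dot-bracket), a total order, so folds are
reproducible. Because every pair energy is negative, the open structure is
optimal iff no legal pair exists — also asserted as a property. Shape:
`hairpin` = ≥ 2 pairs totally ordered by nesting (one terminal loop, bulges
allowed); `open` = ≤ 1 pair (an isolated pair is not a stem; viewers render
such sequences as an unpaired circle); `multiloop` = multiple terminal loops,
possible but rare below 30 nt.

The duplex scanner slides a window (step 1) over a target, and per window
finds the best antiparallel pairing chain under the same energies with
bulges/interior loops ≤ 2 nt per side, by DP, verified against brute-force
chain enumeration. It is a ranking heuristic for candidate binding sites,
deliberately simple; database-backed target prediction and GO enrichment are
out of scope.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 10,000 nt | single circular chromosome (no plasmids) |
| `n_features_per_biotype` | 6 tRNA / 2 rRNA / 4 mRNA / 6 ncRNA | toy features of 76/120/300/80 nt, non-overlapping, random strand |
| `biotype_mixture` | tRF .10, rRNA .10, mRNA .40, ncRNA .05, intergenic .35 | fragment source probabilities |
| `trf_cleavage_offset` | point mass at +2 | fragment 3′ end past the TAGC motif end → 13-nt tRF-5 |
| `length_distributions` | exp decay, scale 6 nt over 8–30 | non-tRF fragment lengths, short-skewed as in degradation pools |
| `omv_loading_weights` | 1.0 for all 8–30 nt | per-length vesicle loading (tests use ×4 for 13–19 nt) |
| `medium_contamination_fraction` | 0.2 | cell-library reads drawn from the medium pool |
| `n_medium_species` | 300 | distinct medium contaminant species, Zipf (1/k) abundances |
| `adapter_seq` | TruSeq small-RNA 3′ adapter | 21 nt |
| `read_length` | 51 | sequencing cycles |

Every tRNA's sense sequence is rejection-sampled so its *first* TAGC starts
at position 8 (1-based), making the cleavage rule unambiguous. Non-tRF
fragments start uniformly within their feature and are clipped at the
feature's 3′ bound (mirroring the observation that mRNA/rRNA fragments map
to scattered positions, unlike tRFs); clipping below 8 nt produces reads the
trimmer discards, exactly as in real libraries. Intergenic fragments are
resampled until they avoid all features. OMV libraries rejection-sample the
cell fragment pool with acceptance ∝ `omv_loading_weights[length]`. The
quantitative ×4 weight for 13–19 nt used in tests is a fixture choice — no
quantitative loading function is established for real vesicles.

The medium is modeled as a *finite species repertoire*: a fixed pool of
`n_medium_species` fragments of an independent random chromosome (disjoint
from the main genome, so subtraction has exact ground truth), with Zipf
abundances. This matters: a sterile medium's RNA content is a limited set of
degradation products, and only because the control library and the cell
contaminants sample the same species can exact-sequence subtraction recover
the contamination rate (with 300 species and Zipf weights, the rarest
species has expected count ≈ 26 in a 50,000-read control, so the control
observes essentially the whole pool). Residual over-removal comes from
chance sequence collisions between short medium species and genuine cell
fragments (~0.3% of counts at the defaults).

Not modeled: sequencing errors, quality scores, PCR duplicates, 5′ adapters,
real tRNA secondary structure or modified bases, strain differences, and any
correlation between fragment abundance and feature identity beyond the
mixture. Passing recovery tests therefore demonstrates the pipeline's
correctness on data satisfying its own assumptions — not robustness to
aligner-tolerance effects, error-containing reads, or the (unpublished)
composition of real libraries, whose headline rates (~7M reads, 34.1%/23%
genome mapping, 41% medium overlap) depend on raw data and settings that are
not reproducible at desk scale and are not targeted.

## Numerical and statistical choices

- **Problem sizes.** Full-scale recovery runs use 100,000 reads per
  compartment; module-level checks use 20,000–50,000 where a binomial bound
  keeps the stated tolerance meaningful (e.g. ±0.01 on a 0.2 fraction is
  > 4σ at n = 30,000). Alignment oracle equivalence uses 1,000 random 8–15-mers
  against a 2,000-nt genome; fold oracle equivalence uses all 40 bundled
  sequences plus 200 random 8–15-mers.
- **Rank agreement for loading recovery.** The configured weight profile is
  two-valued (ties everywhere), so tie-sensitive coefficients are capped well
  below 1 against any noisy observed profile — with 7 of 23 lengths elevated,
  perfect separation gives Spearman ρ = 0.798 and Kendall τ-b = 0.665 by
  construction. Rank agreement is therefore measured as Goodman–Kruskal
  gamma, which scores only comparable (untied) pairs and reaches 1 for
  perfect recovery; `loading_recovery` reports Spearman alongside for
  reference, and the substantive effect (mean elevated/baseline ratio) is
  asserted separately.
- **Determinism.** All randomness flows through numpy `SeedSequence(seed,
  spawn_key)` streams, one per purpose (genome, medium genome, medium pool,
  each compartment), so libraries are independent but byte-identical across
  runs; property tests are seeded or derandomized.
- **Tie-breaks.** Count ties in rankings break lexicographically by sequence;
  annotation ties break by (precedence, leftmost, name); fold ties as above.
  Every ranking the package emits is a total order.
- **Degenerate inputs.** Empty tables skip normalization rather than divide
  by zero; zero-denominator loading ratios are flagged `undefined`, never
  imputed; contigs shorter than the 8-mer seed are indexed as unhittable;
  enumeration and folding refuse sequences > 30 nt.

## Known limitations

Exact-match-only alignment understates mapping rates for error-containing
real reads. Exact-identity medium subtraction removes true-positive cell
sequences that collide with medium species (quantified above) and misses
contaminant species absent from the control. The fold model's energies are
ordinal, not thermodynamic. The duplex scanner has no loop penalties, so
long gappy chains can outscore biologically tighter duplexes on ties. The
generator draws fragment abundance i.i.d. from the mixture, so it cannot
emulate the heavy per-species skew of real top-20 tables; those are covered
by the bundled worked-example data instead.
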