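"""Worked example: recovering length-selective OMV loading.

Simulates paired cell and OMV libraries where 13-19 nt fragments are loaded
into vesicles with 4x weight, then recomputes the per-length OMV/cell RPM
ratio profile and its rank agreement with the configured weights.
"""

from vsrna import SimConfig, make_genome, profile_library, simulate_library
from vsrna.pipeline import loading_recovery
from vsrna.quantify import loading_compare

weights = {L: (4.0 if 13 <= L <= 19 else 1.0) for L in range(8, 31)}
cfg = SimConfig(n_reads=50_000, seed=2, medium_contamination_fraction=0.0,
                omv_loading_weights=weights)
genome, features = make_genome(cfg)
cell_reads, _ = simulate_library(cfg, genome, features, "cell")
omv_reads, _ = simulate_library(cfg, genome, features, "omv")
cell = profile_library(cell_reads, genome, features, cfg.adapter_seq)
omv = profile_library(omv_reads, genome, features, cfg.adapter_seq)

comp = loading_compare(cell.table, omv.table)
print("length  OMV/cell RPM ratio")
for L in sorted(comp.ratio):
    bar = "#" * int(round(comp.ratio[L] * 10))
    tag = " <- elevated" if 13 <= L <= 19 else ""
    print(f"{L:6d}  {comp.ratio[L]:6.2f} {bar}{tag}")

rec = loading_recovery(cell.table, omv.table, weights)
print(f"rank agreement with configured weights (gamma): {rec['gamma']:.3f}")
print(f"mean ratio, elevated (13-19 nt) vs baseline lengths: "
      f"{rec['elevated_vs_baseline']:.2f}")

# Both libraries are normalized to their own totals, so the absolute ratio
# level is arbitrary; what reproduces the configured loading is the ~4x
# contrast between elevated and baseline lengths, and gamma ~1 (the profile
# ranks the lengths exactly as the weights do).
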