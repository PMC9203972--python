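"""The synthetic-data generator: determinism, post-conditions, calibration."""

import numpy as np
import pytest
from scipy import stats

from vsrna.annotate import D_ARM_MOTIF
from vsrna.simulate import (
    FEATURE_LENGTHS,
    MOTIF_START,
    PlacementError,
    SimConfig,
    make_genome,
    make_medium_genome,
    make_medium_pool,
    simulate_library,
    write_simulation,
)


class TestSimConfig:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="biotype_mixture"):
            SimConfig(biotype_mixture={"tRF": 0.5, "mRNA": 0.4})

    def test_loading_weights_must_cover_8_to_30(self):
        with pytest.raises(ValueError, match="missing lengths"):
            SimConfig(omv_loading_weights={L: 1.0 for L in range(8, 30)})

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="not all"):
            SimConfig(omv_loading_weights={L: 0.0 for L in range(8, 31)})

    def test_contamination_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(medium_contamination_fraction=1.5)

    def test_adapter_alphabet_and_length(self):
        with pytest.raises(ValueError):
            SimConfig(adapter_seq="ACGTACG")  # too short


class TestMakeGenome:
    def test_trna_sense_carries_motif_at_position_8(self):
        cfg = SimConfig(genome_length=500, n_features_per_biotype={"tRNA": 1}, seed=1)
        genome, features = make_genome(cfg)
        (trna,) = features
        sense = trna.sense_seq(genome)
        assert sense[MOTIF_START : MOTIF_START + 4] == D_ARM_MOTIF  # 1-based 8-11
        assert sense.find(D_ARM_MOTIF) == MOTIF_START

    def test_no_features_random_genome(self):
        cfg = SimConfig(genome_length=300, n_features_per_biotype={}, seed=3)
        genome, features = make_genome(cfg)
        assert features == [] and len(genome["chrom"]) == 300

    def test_features_non_overlapping_with_declared_lengths(self, small_sim):
        _, genome, features = small_sim
        spans = sorted((f.start, f.end) for f in features)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for f in features:
            assert f.length == FEATURE_LENGTHS[f.biotype]

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            make_genome(SimConfig(genome_length=600,
                                  n_features_per_biotype={"mRNA": 50}))

    def test_determinism_byte_identical_outputs(self, tmp_path):
        cfg = dict(n_reads=300, seed=7)
        p1 = write_simulation(tmp_path / "a", SimConfig(**cfg))
        p2 = write_simulation(tmp_path / "b", SimConfig(**cfg))
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestSimulateLibrary:
    def test_pure_trf_mixture_all_13nt_flush(self):
        cfg = SimConfig(
            n_reads=500,
            seed=5,
            biotype_mixture={"tRF": 1.0},
            medium_contamination_fraction=0.0,
        )
        genome, features = make_genome(cfg)
        trna_starts = {
            f.name: f.sense_seq(genome)[:13] for f in features if f.biotype == "tRNA"
        }
        reads, truth = simulate_library(cfg, genome, features, "cell")
        assert set(truth.df["fragment_length"]) == {13}
        for read, src in zip(reads, truth.df["source_feature"]):
            assert read.seq[:13] == trna_starts[src]
            assert read.seq[13:] == cfg.adapter_seq[: len(read.seq) - 13]

    def test_uniform_loading_weights_cell_omv_histograms_agree(self):
        """Chi-square on per-length counts, n=50,000 per compartment."""
        cfg = SimConfig(n_reads=50_000, seed=13, medium_contamination_fraction=0.0)
        genome, features = make_genome(cfg)
        _, t_cell = simulate_library(cfg, genome, features, "cell")
        _, t_omv = simulate_library(cfg, genome, features, "omv")
        lengths = np.arange(8, 31)
        obs = np.array([
            [np.sum(t_cell.df["fragment_length"] == L) for L in lengths],
            [np.sum(t_omv.df["fragment_length"] == L) for L in lengths],
        ])
        obs = obs[:, obs.sum(axis=0) > 0]
        _, p, _, _ = stats.chi2_contingency(obs)
        assert p > 0.01

    def test_contamination_fraction_realized(self):
        cfg = SimConfig(n_reads=30_000, seed=21, medium_contamination_fraction=0.2)
        genome, features = make_genome(cfg)
        _, truth = simulate_library(cfg, genome, features, "cell")
        # binomial: sd ~ 0.0023 at n=30k, so +-0.01 is > 4 sigma
        assert truth.contaminant_fraction() == pytest.approx(0.2, abs=0.01)

    def test_zero_contamination_no_flagged_reads(self):
        cfg = SimConfig(n_reads=2000, seed=2, medium_contamination_fraction=0.0)
        genome, features = make_genome(cfg)
        _, truth = simulate_library(cfg, genome, features, "cell")
        assert not truth.df["is_medium_contaminant"].any()

    def test_medium_reads_come_from_medium_pool(self):
        cfg = SimConfig(n_reads=1000, seed=4)
        genome, features = make_genome(cfg)
        species, _ = make_medium_pool(cfg)
        reads, truth = simulate_library(cfg, genome, features, "medium")
        assert set(truth.df["biotype"]) == {"medium"}
        pool = set(species)
        for read, L in zip(reads, truth.df["fragment_length"]):
            assert read.seq[:L] in pool

    def test_realized_mixture_within_binomial_bounds(self):
        """Realized source fractions sit within 5 sigma of the configured mixture."""
        cfg = SimConfig(n_reads=20_000, seed=9, medium_contamination_fraction=0.0)
        genome, features = make_genome(cfg)
        _, truth = simulate_library(cfg, genome, features, "cell")
        frac = truth.mixture_fractions()
        for b, p in cfg.biotype_mixture.items():
            sigma = np.sqrt(p * (1 - p) / cfg.n_reads)
            assert abs(frac.get(b, 0.0) - p) < 5 * sigma

    def test_unknown_compartment_rejected(self, small_sim):
        cfg, genome, features = small_sim
        with pytest.raises(ValueError):
            simulate_library(cfg, genome, features, "plasma")

    def test_medium_genome_distinct_from_main(self, small_sim):
        cfg, genome, _ = small_sim
        assert make_medium_genome(cfg)["medium"] != genome["chrom"]
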