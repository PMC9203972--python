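"""Synthetic genomes, annotations, and cell/OMV/medium read libraries.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without sequencing data:

* a single random chromosome carrying non-overlapping toy features
  (tRNA 76 nt, rRNA 120 nt, mRNA 300 nt, ncRNA 80 nt) on random strands,
  with every tRNA forced to carry the D-arm cleavage motif TAGC at sense
  positions 8-11;
* tRNA-derived fragments cut at the motif: the fragment runs from the
  mature tRNA's 5' end to (motif end + offset), the default point mass at
  offset 2 yielding the canonical 13-nt tRF-5 product;
* non-tRF fragments sampled uniformly within their feature with a
  short-skewed length distribution over 8-30 nt, as in a
  degradation-derived fragment pool;
* OMV libraries drawn from the same fragment pool reweighted per length
  (selective loading), via rejection sampling;
* an independent "medium" chromosome feeding a sterile-medium control
  library, and contaminating the cell library at a configurable rate;
* reads = fragment + 3' adapter, truncated to the read length (default 51
  cycles), with a per-read ground-truth record.

Identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .align import revcomp
from .annotate import D_ARM_MOTIF, Feature
from .io import ReadRecord, write_fasta, write_fastq, write_gff3

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PlacementError",
    "FEATURE_LENGTHS",
    "MOTIF_START",
    "make_genome",
    "make_medium_genome",
    "make_medium_pool",
    "simulate_library",
    "default_length_distribution",
    "write_simulation",
]

FEATURE_LENGTHS = {"tRNA": 76, "rRNA": 120, "mRNA": 300, "ncRNA": 80}
#: 0-based start of the forced TAGC motif on every tRNA's sense strand
MOTIF_START = 7
MOTIF_END = MOTIF_START + len(D_ARM_MOTIF)  # 0-based exclusive = 11

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_AMINO_ACIDS = ["Ile", "Ala", "Pro", "Gly", "Val", "Leu", "Ser", "Thr", "Lys", "Arg"]

Compartment = Literal["cell", "omv", "medium"]


class PlacementError(RuntimeError):
    """Features could not be placed without overlap in the requested genome."""


def default_length_distribution(decay: float = 6.0) -> dict[int, float]:
    """Short-skewed fragment-length distribution over 8-30 nt.

    Truncated geometric decay, p(L) proportional to exp(-(L-8)/decay):
    fragment pools from nucleolytic degradation are dominated by the
    shortest retained species.
    """
    w = {L: float(np.exp(-(L - 8) / decay)) for L in range(8, 31)}
    z = sum(w.values())
    return {L: v / z for L, v in w.items()}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    genome_length: int = 10_000
    n_features_per_biotype: dict[str, int] = field(
        default_factory=lambda: {"tRNA": 6, "rRNA": 2, "mRNA": 4, "ncRNA": 6}
    )
    #: fragment-source mixture; "tRF" = motif-cut tRNA fragments,
    #: "intergenic" = fragments from unannotated genome
    biotype_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "tRF": 0.10,
            "rRNA": 0.10,
            "mRNA": 0.40,
            "ncRNA": 0.05,
            "intergenic": 0.35,
        }
    )
    #: distribution of the fragment 3'-end offset past the motif end;
    #: offset 2 with the motif at 8-11 gives a 13-nt fragment
    trf_cleavage_offset: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    #: per-biotype fragment-length distributions over 8-30 nt (tRF excluded:
    #: its length follows from the cleavage rule)
    length_distributions: dict[str, dict[int, float]] | None = None
    #: relative OMV loading weight per fragment length 8-30
    omv_loading_weights: dict[int, float] = field(
        default_factory=lambda: {L: 1.0 for L in range(8, 31)}
    )
    medium_contamination_fraction: float = 0.2
    #: number of distinct contaminant species in the medium RNA pool; their
    #: abundances follow a Zipf law (rank k gets weight 1/k). A sterile
    #: culture medium carries a finite repertoire of degradation products,
    #: which is what makes subtraction by exact sequence identity effective.
    n_medium_species: int = 300
    adapter_seq: str = DEFAULT_ADAPTER
    read_length: int = 51
    n_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.biotype_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"biotype_mixture sums to {tot}, expected 1")
        if any(p < 0 or p > 1 for p in self.biotype_mixture.values()):
            raise ValueError("biotype_mixture probabilities must be in [0, 1]")
        missing = [L for L in range(8, 31) if L not in self.omv_loading_weights]
        if missing:
            raise ValueError(f"omv_loading_weights missing lengths {missing}")
        if any(w < 0 for w in self.omv_loading_weights.values()):
            raise ValueError("omv_loading_weights must be >= 0")
        if all(w == 0 for w in self.omv_loading_weights.values()):
            raise ValueError("omv_loading_weights must not all be 0")
        if not 0 <= self.medium_contamination_fraction <= 1:
            raise ValueError("medium_contamination_fraction must be in [0, 1]")
        if len(self.adapter_seq) < 10 or set(self.adapter_seq) - set("ACGT"):
            raise ValueError("adapter_seq must be >= 10 nt over {A,C,G,T}")
        if self.length_distributions is None:
            dist = default_length_distribution()
            self.length_distributions = {
                b: dict(dist) for b in ("rRNA", "mRNA", "ncRNA", "intergenic", "medium")
            }


@dataclass
class SyntheticTruth:
    """Per-read provenance: one row per emitted read.

    Columns: read_id, compartment, biotype (tRF/rRNA/mRNA/ncRNA/intergenic/
    medium), source_feature, fragment_length, is_medium_contaminant.
    """

    df: pd.DataFrame

    def mixture_fractions(self) -> pd.Series:
        """Realized source fractions among non-contaminant reads."""
        clean = self.df[~self.df["is_medium_contaminant"]]
        return clean["biotype"].value_counts(normalize=True).sort_index()

    def contaminant_fraction(self) -> float:
        return float(self.df["is_medium_contaminant"].mean())

    def length_profile(self) -> pd.Series:
        return self.df["fragment_length"].value_counts(normalize=True).sort_index()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


_STREAM = {
    "genome": 0,
    "medium_genome": 1,
    "cell": 2,
    "omv": 3,
    "medium": 4,
    "medium_pool": 5,
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _trna_sense(rng: np.random.Generator) -> str:
    """Random 76-nt tRNA sense sequence whose first TAGC starts at position 8.

    Rejection-sampled so the motif occurrence inside the canonical fragment
    window is unique, keeping the cleavage rule unambiguous.
    """
    n = FEATURE_LENGTHS["tRNA"]
    while True:
        s = list(_random_seq(rng, n))
        s[MOTIF_START:MOTIF_END] = D_ARM_MOTIF
        seq = "".join(s)
        if seq.find(D_ARM_MOTIF) == MOTIF_START:
            return seq


def make_genome(config: SimConfig) -> tuple[dict[str, str], list[Feature]]:
    """One random chromosome with non-overlapping annotated features.

    Raises PlacementError when the features cannot be placed (the config
    precondition genome_length >= 50 x feature count is also enforced).
    """
    n_feat = sum(config.n_features_per_biotype.values())
    if config.genome_length < 50 * n_feat:
        raise PlacementError(
            f"genome_length {config.genome_length} < 50 x {n_feat} features"
        )
    rng = _rng(config, _STREAM["genome"])
    genome = list(_random_seq(rng, config.genome_length))
    placed: list[tuple[int, int]] = []
    features: list[Feature] = []
    counters: dict[str, int] = {}
    for biotype in ("tRNA", "rRNA", "mRNA", "ncRNA"):
        for _ in range(config.n_features_per_biotype.get(biotype, 0)):
            flen = FEATURE_LENGTHS[biotype]
            if flen > config.genome_length:
                raise PlacementError(f"{biotype} ({flen} nt) longer than genome")
            for _try in range(1000):
                start = int(rng.integers(0, config.genome_length - flen + 1))
                if all(start >= e or start + flen <= s for s, e in placed):
                    break
            else:
                raise PlacementError(
                    f"could not place {biotype} feature after 1000 attempts"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            idx = counters.get(biotype, 0)
            counters[biotype] = idx + 1
            if biotype == "tRNA":
                aa = _AMINO_ACIDS[idx % len(_AMINO_ACIDS)]
                rep = idx // len(_AMINO_ACIDS)
                name = f"tRNA-{aa}" + (f"-{rep + 1}" if rep else "")
                sense = _trna_sense(rng)
            else:
                name = f"{biotype}-{idx + 1}"
                sense = _random_seq(rng, flen)
            embedded = sense if strand == "+" else revcomp(sense)
            genome[start : start + flen] = embedded
            placed.append((start, start + flen))
            features.append(
                Feature("chrom", start, start + flen, strand, biotype, name)
            )
    features.sort(key=lambda f: f.start)
    return {"chrom": "".join(genome)}, features


def make_medium_genome(config: SimConfig) -> dict[str, str]:
    """Independent random chromosome feeding the sterile-medium library.

    A separate sequence, disjoint from the main chromosome, so contaminant
    subtraction has an unambiguous ground truth.
    """
    rng = _rng(config, _STREAM["medium_genome"])
    return {"medium": _random_seq(rng, config.genome_length)}


def make_medium_pool(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """The medium's contaminant species and their cumulative Zipf abundances.

    Species are fragments of the medium chromosome (random position, strand
    and length); the pool is a deterministic function of (config, seed), so
    the sterile-medium library and the contaminants injected into the cell
    library sample the very same species.
    """
    rng = _rng(config, _STREAM["medium_pool"])
    chrom = make_medium_genome(config)["medium"]
    assert config.length_distributions is not None
    keys, cum = _cum(config.length_distributions["medium"])
    species: list[str] = []
    for _ in range(config.n_medium_species):
        L = _draw(rng, keys, cum)
        start = int(rng.integers(0, len(chrom) - L + 1))
        frag = chrom[start : start + L]
        species.append(frag if rng.random() < 0.5 else revcomp(frag))
    weights = 1.0 / np.arange(1, config.n_medium_species + 1)
    return species, np.cumsum(weights / weights.sum())


def _cum(dist: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys, np.cumsum(probs / probs.sum())


def _draw(rng: np.random.Generator, keys: np.ndarray, cum: np.ndarray) -> int:
    return int(keys[np.searchsorted(cum, rng.random(), side="right")])


def simulate_library(
    config: SimConfig,
    genome: dict[str, str],
    features: Sequence[Feature],
    compartment: Compartment,
) -> tuple[list[ReadRecord], SyntheticTruth]:
    """Simulate one sequencing library for a compartment.

    cell: fragments drawn per ``biotype_mixture`` plus medium contaminants
    at ``medium_contamination_fraction``. omv: same fragment pool, each
    candidate accepted with probability proportional to
    ``omv_loading_weights[length]`` (rejection sampling). medium: fragments
    from the independent medium chromosome only.

    Reads are fragment + adapter truncated to ``read_length``; shorter reads
    keep the full adapter remainder. Deterministic given (config, seed).
    """
    if compartment not in ("cell", "omv", "medium"):
        raise ValueError(f"unknown compartment {compartment!r}")
    rng = _rng(config, _STREAM[compartment])
    chrom = genome["chrom"]
    assert config.length_distributions is not None
    dists = {b: _cum(d) for b, d in config.length_distributions.items()}
    mix_names = sorted(config.biotype_mixture)
    mix_keys = np.arange(len(mix_names))
    mix_cum = np.cumsum(
        np.array([config.biotype_mixture[b] for b in mix_names]) /
        sum(config.biotype_mixture.values())
    )
    off_keys, off_cum = _cum({int(k): v for k, v in config.trf_cleavage_offset.items()})
    trnas = [f for f in features if f.biotype == "tRNA"]
    by_biotype = {
        b: [f for f in features if f.biotype == b] for b in ("rRNA", "mRNA", "ncRNA")
    }
    if config.biotype_mixture.get("tRF", 0) > 0 and not trnas:
        raise ValueError("mixture requests tRFs but the genome has no tRNA features")
    for b in ("rRNA", "mRNA", "ncRNA"):
        if config.biotype_mixture.get(b, 0) > 0 and not by_biotype[b]:
            raise ValueError(f"mixture requests {b} but the genome has no {b} features")
    sense_cache = {f.name: f.sense_seq(genome) for f in features}
    wmax = max(config.omv_loading_weights.values())

    med_species, med_cum = make_medium_pool(config)

    def medium_fragment() -> tuple[str, str]:
        k = int(np.searchsorted(med_cum, rng.random(), side="right"))
        return med_species[k], f"medium_{k}"

    def genomic_fragment() -> tuple[str, str, str]:
        """One fragment from the mixture: (seq, truth biotype, source name)."""
        b = mix_names[_draw(rng, mix_keys, mix_cum)]
        if b == "tRF":
            f = trnas[int(rng.integers(0, len(trnas)))]
            off = _draw(rng, off_keys, off_cum)
            end = min(MOTIF_END + off, f.length)
            return sense_cache[f.name][:end], "tRF", f.name
        if b == "intergenic":
            keys, cum = dists["intergenic"]
            while True:
                L = _draw(rng, keys, cum)
                start = int(rng.integers(0, len(chrom) - L + 1))
                if all(start >= f.end or start + L <= f.start for f in features):
                    break
            frag = chrom[start : start + L]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            return frag, "intergenic", "intergenic"
        f = by_biotype[b][int(rng.integers(0, len(by_biotype[b])))]
        keys, cum = dists[b]
        L = _draw(rng, keys, cum)
        start = int(rng.integers(0, f.length))
        return sense_cache[f.name][start : start + L], b, f.name

    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    for i in range(config.n_reads):
        contaminant = False
        if compartment == "medium":
            frag, source = medium_fragment()
            biotype = "medium"
        elif compartment == "cell":
            if rng.random() < config.medium_contamination_fraction:
                (frag, source), biotype = medium_fragment(), "medium"
                contaminant = True
            else:
                frag, biotype, source = genomic_fragment()
        else:  # omv: rejection-sample the cell pool by loading weight
            while True:
                frag, biotype, source = genomic_fragment()
                L = min(max(len(frag), 8), 30)
                if rng.random() * wmax < config.omv_loading_weights[L]:
                    break
        seq = (frag + config.adapter_seq)[: config.read_length]
        rid = f"{compartment}_{i}"
        reads.append(ReadRecord(rid, seq, "I" * len(seq)))
        rows.append((rid, compartment, biotype, source, len(frag), contaminant))
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "compartment",
            "biotype",
            "source_feature",
            "fragment_length",
            "is_medium_contaminant",
        ],
    )
    return reads, SyntheticTruth(truth)


def write_simulation(
    out_dir: str | Path,
    config: SimConfig,
    compartments: Iterable[Compartment] = ("cell", "omv", "medium"),
) -> dict[str, Path]:
    """Run the generator and write FASTA/GFF3/FASTQ/TSV files to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, features = make_genome(config)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["medium_genome"] = out / "medium_genome.fa"
    write_fasta(make_medium_genome(config), paths["medium_genome"])
    paths["features"] = out / "features.gff3"
    write_gff3(features, paths["features"])
    for comp in compartments:
        reads, truth = simulate_library(config, genome, features, comp)
        paths[f"{comp}_reads"] = out / f"{comp}.fastq"
        write_fastq(reads, paths[f"{comp}_reads"])
        paths[f"{comp}_truth"] = out / f"{comp}_truth.tsv"
        truth.df.to_csv(paths[f"{comp}_truth"], sep="\t", index=False)
    return paths
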