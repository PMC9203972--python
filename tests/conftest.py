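"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately reimplement operations in the dumbest possible
way (sliding-window scans, subset enumeration) so the package's indexed /
dynamic-programming implementations can be checked against them.
"""

from __future__ import annotations

import random

import pytest

from vsrna.align import Hit, revcomp
from vsrna.annotate import Feature
from vsrna.simulate import SimConfig, make_genome

# --- brute-force oracles ------------------------------------------------


def oracle_align(seq: str, genome: dict[str, str]) -> list[Hit]:
    """All exact placements by naive double-strand sliding-window scan."""
    hits: set[Hit] = set()
    for contig, ref in genome.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            pos = ref.find(s)
            while pos != -1:
                hits.add(Hit(contig, pos, pos + len(s), strand, seq))
                pos = ref.find(s, pos + 1)
    return sorted(hits, key=lambda h: (h.contig, h.start, h.strand))


PAIR_E = {frozenset("GC"): -3, frozenset("AU"): -2, frozenset("GU"): -1}


def oracle_structures(rna: str, min_loop: int = 3) -> set[frozenset]:
    """All valid nested pair sets by subset enumeration over candidate pairs.

    Exponential in the number of candidate pairs; use on short sequences only.
    """
    n = len(rna)
    cands = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + min_loop + 1, n + 1)
        if frozenset((rna[i - 1], rna[j - 1])) in PAIR_E
    ]

    def compatible(p, q):
        i1, j1 = p
        i2, j2 = q
        if {i1, j1} & {i2, j2}:
            return False
        # crossing: i1 < i2 < j1 < j2 (either order)
        if i1 < i2 < j1 < j2 or i2 < i1 < j2 < j1:
            return False
        return True

    out: set[frozenset] = set()

    def rec(idx: int, chosen: tuple):
        if idx == len(cands):
            out.add(frozenset(chosen))
            return
        rec(idx + 1, chosen)
        p = cands[idx]
        if all(compatible(p, q) for q in chosen):
            rec(idx + 1, chosen + (p,))

    rec(0, ())
    return out


def oracle_duplex_energy(q: str, w: str, max_gap: int = 2) -> int:
    """Best antiparallel duplex energy by exhaustive chain enumeration.

    Chains of pairs (i, j) with i strictly increasing, j strictly
    decreasing, and at most ``max_gap`` skipped bases per side between
    consecutive pairs. Exponential; use on short inputs.
    """
    m, n = len(q), len(w)
    best = 0

    def extend(i: int, j: int, acc: int):
        nonlocal best
        best = min(best, acc)
        for di in range(1, max_gap + 2):
            for dj in range(1, max_gap + 2):
                i2, j2 = i + di, j - dj
                if i2 < m and j2 >= 0:
                    e = PAIR_E.get(frozenset((q[i2], w[j2])))
                    if e is not None:
                        extend(i2, j2, acc + e)

    for i in range(m):
        for j in range(n):
            e = PAIR_E.get(frozenset((q[i], w[j])))
            if e is not None:
                extend(i, j, e)
    return best


# --- fixtures -----------------------------------------------------------

#: the most abundant Ile-tRF in the bundled OMV table; its TAGC motif sits
#: at positions 8-11 so the 13-nt fragment is the canonical cleavage product
ILE_TRF = "AGGCTTGTAGCTC"
ALA_TRF = "GGGGCTATAGCTC"


def _random_seq(rng: random.Random, n: int, forbid: str | None = None) -> str:
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if forbid is None or (forbid not in s and forbid not in revcomp(s)):
            return s


@pytest.fixture(scope="session")
def ile_fixture():
    """A 400-nt genome with one plus-strand tRNA whose 5' end is the Ile-tRF.

    The background is rejection-sampled so the 13-mer occurs nowhere else;
    align_seq(ILE_TRF) must return exactly one hit, flush with the feature
    5' boundary.
    """
    rng = random.Random(2024)
    trna_sense = ILE_TRF + _random_seq(rng, 63, forbid="TAGC")
    assert trna_sense.find("TAGC") == 7
    left = _random_seq(rng, 100, forbid=ILE_TRF)
    right = _random_seq(rng, 224, forbid=ILE_TRF)
    genome = {"chrom": left + trna_sense + right}
    trna = Feature("chrom", 100, 176, "+", "tRNA", "tRNA-Ile")
    assert genome["chrom"].count(ILE_TRF) == 1
    return genome, [trna]


@pytest.fixture(scope="session")
def minus_trna_fixture():
    """A genome with one minus-strand tRNA (hand-enumerated coordinates).

    The tRNA occupies [50, 126); its biological 5' end is genomic position
    125 (the right edge), so a flush tRF-5 hit of length 13 spans [113, 126)
    on the minus strand.
    """
    rng = random.Random(99)
    sense = ILE_TRF + _random_seq(rng, 63, forbid="TAGC")
    genome_seq = _random_seq(rng, 50, forbid=ILE_TRF) + revcomp(sense) + _random_seq(
        rng, 80, forbid=ILE_TRF
    )
    genome = {"chrom": genome_seq}
    trna = Feature("chrom", 50, 126, "-", "tRNA", "tRNA-Ile")
    return genome, [trna]


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulation shared across tests."""
    cfg = SimConfig(n_reads=5000, seed=11, medium_contamination_fraction=0.0)
    genome, features = make_genome(cfg)
    return cfg, genome, features
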