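"""Secondary structure of ultrashort RNAs under an exactly solvable pair model.

Sequences this short (<= 30 nt) admit exhaustive treatment, so instead of a
Turner-parameter thermodynamic model the package uses a bespoke integer pair
energy — e(G-C) = -3, e(A-U) = -2, e(G-U) = -1 model units, nested pairs
only, minimum hairpin loop of 3 — which preserves the qualitative chemistry
(G-C pairs stabilize stems most, wobble pairs least) while every quantity it
defines can be verified by literally enumerating all structures. Energies
are model units, not kcal/mol.

A fragment folds into a "hairpin" when its optimal structure has a single
stem-loop of at least two pairs; a fragment with at most one isolated pair
is "open" (rendered as a circle of unpaired bases by structure viewers).

``duplex_scan`` is a deliberately simple intermolecular hybridization
scanner with the same pair energies: antiparallel pairing between a query
and target windows, interior loops/bulges up to 2 nt per side, no loop
penalty terms. It ranks candidate binding sites; it is not a substitute for
a full hybridization thermodynamics tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

__all__ = [
    "PAIR_ENERGY",
    "SecondaryStructure",
    "DuplexHit",
    "to_rna",
    "enumerate_structures",
    "structure_energy",
    "mfe_fold",
    "classify_shape",
    "duplex_scan",
    "MAX_FOLD_LEN",
    "MIN_LOOP",
]

MAX_FOLD_LEN = 30
MIN_LOOP = 3

#: pair energies in model units (all stabilizing)
PAIR_ENERGY = {
    frozenset("GC"): -3,
    frozenset("AU"): -2,
    frozenset("GU"): -1,
}


def to_rna(seq: str) -> str:
    """Normalize a DNA/RNA string to the RNA alphabet (T -> U, uppercase)."""
    return seq.upper().replace("T", "U")


def _pair_e(a: str, b: str) -> int | None:
    return PAIR_ENERGY.get(frozenset((a, b)))


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]]) -> int:
    """Summed pair energy of a structure; pairs are 1-based (i, j), i < j."""
    total = 0
    for i, j in pairs:
        e = _pair_e(seq[i - 1], seq[j - 1])
        if e is None:
            raise ValueError(f"illegal pair {seq[i - 1]}-{seq[j - 1]} at ({i},{j})")
        total += e
    return total


def _dot_bracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return "".join(db)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested base-pair set with its model energy and shape class."""

    seq: str
    pairs: frozenset[tuple[int, int]]  # 1-based, i < j
    energy: int
    shape: str  # hairpin | open | multiloop
    gc_pairs: int
    dot_bracket: str


def enumerate_structures(
    seq: str, min_loop: int = MIN_LOOP
) -> list[frozenset[tuple[int, int]]]:
    """Every valid nested pair set of ``seq``, including the empty structure.

    Valid means: pairs drawn from {G-C, A-U, G-U}, non-crossing, each base in
    at most one pair, and j - i - 1 >= min_loop for every pair (i, j).
    Enumeration is exponential, so a 30-nt guard is enforced.
    """
    rna = to_rna(seq)
    n = len(rna)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence length {n} exceeds enumeration guard {MAX_FOLD_LEN}")

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        # all structures on the 1-based closed interval [i, j]
        if i > j:
            return [()]
        out = [s for s in rec(i + 1, j)]  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if _pair_e(rna[i - 1], rna[k - 1]) is not None:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return out

    return [frozenset(s) for s in rec(1, n)]


def _shape_of(pairs: frozenset[tuple[int, int]]) -> str:
    if len(pairs) <= 1:
        return "open"
    ordered = sorted(pairs)
    for (i1, j1), (i2, j2) in zip(ordered, ordered[1:]):
        if not (i1 < i2 and j2 < j1):  # successive pairs must nest
            return "multiloop"
    return "hairpin"


def _structure(seq_rna: str, pairs: frozenset[tuple[int, int]]) -> SecondaryStructure:
    gc = sum(1 for i, j in pairs if frozenset((seq_rna[i - 1], seq_rna[j - 1])) == frozenset("GC"))
    return SecondaryStructure(
        seq=seq_rna,
        pairs=pairs,
        energy=structure_energy(seq_rna, sorted(pairs)),
        shape=_shape_of(pairs),
        gc_pairs=gc,
        dot_bracket=_dot_bracket(len(seq_rna), sorted(pairs)),
    )


def mfe_fold(seq: str, min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Minimum-energy structure by interval dynamic programming.

    Optimizes the triple (energy, number of pairs, dot-bracket string)
    lexicographically, so ties at the minimum energy resolve to the structure
    with fewest pairs, then to the lexicographically smallest dot-bracket —
    a total, reproducible order. Verified against ``enumerate_structures``
    in the test suite.
    """
    rna = to_rna(seq)
    n = len(rna)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence length {n} exceeds fold guard {MAX_FOLD_LEN}")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, int, str]:
        # (energy, n_pairs, dot_bracket) for 1-based closed interval [i, j]
        if i > j:
            return (0, 0, "")
        e1, p1, d1 = best(i + 1, j)
        cand = (e1, p1, "." + d1)
        for k in range(i + min_loop + 1, j + 1):
            e_pair = _pair_e(rna[i - 1], rna[k - 1])
            if e_pair is None:
                continue
            ein, pin, din = best(i + 1, k - 1)
            eout, pout, dout = best(k + 1, j)
            c = (e_pair + ein + eout, 1 + pin + pout, "(" + din + ")" + dout)
            if c < cand:
                cand = c
        return cand

    _, _, db = best(1, n)
    best.cache_clear()
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db, 1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.add((stack.pop(), pos))
    return _structure(rna, frozenset(pairs))


def classify_shape(structure: SecondaryStructure) -> str:
    """Shape class: hairpin (single stem-loop, >= 2 pairs), open, or multiloop.

    A lone isolated pair is not a stem and classifies as open.
    """
    return _shape_of(structure.pairs)


# --- intermolecular duplex scan ----------------------------------------


@dataclass(frozen=True)
class DuplexHit:
    """Best antiparallel duplex between a query and one target window."""

    query: str
    target_window: str
    target_pos: int  # 0-based window start on the target
    pairs: tuple[tuple[int, int], ...]  # (query pos, window pos), 1-based
    duplex_energy: int


def _best_duplex(q: str, w: str) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Best (most negative) antiparallel duplex energy and its pairing.

    D[i][j]: best duplex whose first pair is (q[i], w[j]); subsequent pairs
    advance the query and retreat on the window with gaps of at most 2 nt
    per side (interior loops/bulges <= 2).
    """
    m, n = len(q), len(w)
    energy = [[0] * n for _ in range(m)]
    nxt: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(m)]
    best_e, best_ij = 0, None
    for i in range(m - 1, -1, -1):
        for j in range(n):
            e = _pair_e(q[i], w[j])
            if e is None:
                energy[i][j] = 0
                continue
            tail, tail_ij = 0, None
            for di in range(1, 4):
                for dj in range(1, 4):
                    i2, j2 = i + di, j - dj
                    # a continuation must itself be a paired cell (energy < 0)
                    if i2 < m and j2 >= 0 and energy[i2][j2] < tail:
                        tail, tail_ij = energy[i2][j2], (i2, j2)
            energy[i][j] = e + tail
            nxt[i][j] = tail_ij if tail_ij is not None else (-1, -1)
            if energy[i][j] < best_e:
                best_e, best_ij = energy[i][j], (i, j)
    if best_ij is None:
        return 0, ()
    pairs = []
    ij: tuple[int, int] | None = best_ij
    while ij is not None and ij != (-1, -1):
        pairs.append((ij[0] + 1, ij[1] + 1))
        ij = nxt[ij[0]][ij[1]]
    return int(best_e), tuple(pairs)


def duplex_scan(vsrna: str, target: str, window: int | None = None) -> list[DuplexHit]:
    """Scan a target for binding sites of a short RNA (sliding windows, step 1).

    Per window, the best antiparallel duplex under the pair-energy model with
    bulges/interior loops <= 2 nt per side. Windows with no possible pair
    (energy 0) yield no hit. Hits are sorted by energy (most stable first),
    ties by target position.
    """
    q = to_rna(vsrna)
    t = to_rna(target)
    if window is None:
        window = len(q)
    if window < len(q):
        raise ValueError(f"window ({window}) must be >= query length ({len(q)})")
    hits = []
    for pos in range(0, max(1, len(t) - window + 1)):
        w = t[pos : pos + window]
        e, pairs = _best_duplex(q, w)
        if e < 0:
            hits.append(DuplexHit(q, w, pos, pairs, e))
    return sorted(hits, key=lambda h: (h.duplex_energy, h.target_pos))
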