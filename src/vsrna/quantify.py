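"""Normalization, medium subtraction, length/loading comparisons, top-N tables.

Abundances are tag counts per million (CPM): a unique sequence's read count
scaled by the library total, with no feature-length normalization — the unit
of measurement is the sequence itself, not a gene model. "RPM" is the same
quantity under another name and both labels are accepted where a basis
string is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedCountTable",
    "LengthDistribution",
    "LoadingComparison",
    "cpm_normalize",
    "subtract_medium",
    "length_profile",
    "biotype_composition",
    "loading_compare",
    "top_n",
    "family_abundance",
    "family_enrichment",
    "round_half_away",
    "VSRNA_WINDOW",
    "SRNA_WINDOW",
]

VSRNA_WINDOW = (8, 15)  # very small RNAs, below the conventional sRNA-seq cutoff
SRNA_WINDOW = (16, 30)

_COLUMNS = ["seq", "count", "cpm", "biotype", "family", "length"]


@dataclass
class AnnotatedCountTable:
    """Per-unique-sequence counts with CPM, biotype, family and length.

    Wraps a DataFrame with columns seq, count, cpm, biotype, family, length;
    ``library_total`` is the denominator used for CPM (the sum of counts of
    the table as normalized, which may exceed the current row sum after
    truncation to a top-N extract).
    """

    df: pd.DataFrame
    library_total: int

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple], normalized: bool = True
    ) -> "AnnotatedCountTable":
        """Build from (seq, count, biotype, family) tuples and CPM-normalize."""
        df = pd.DataFrame(rows, columns=["seq", "count", "biotype", "family"])
        df["length"] = df["seq"].str.len()
        df["cpm"] = np.nan
        table = cls(df[_COLUMNS].copy(), library_total=int(df["count"].sum()))
        return cpm_normalize(table) if normalized else table

    def __len__(self) -> int:
        return len(self.df)


def cpm_normalize(table: AnnotatedCountTable) -> AnnotatedCountTable:
    """Recompute CPM on the table's own count total; counts untouched.

    An empty table is returned unchanged (no division by zero); otherwise
    CPM sums to 1e6 over the full table.
    """
    df = table.df.copy()
    total = int(df["count"].sum())
    if total == 0:
        return AnnotatedCountTable(df, 0)
    df["cpm"] = df["count"] / total * 1e6
    return AnnotatedCountTable(df, total)


def subtract_medium(
    table: AnnotatedCountTable, medium_seqs: Iterable[str]
) -> tuple[AnnotatedCountTable, float]:
    """Remove sequences also observed in the culture-medium control.

    Exact sequence identity, not alignment: a read is a contaminant when the
    very same sequence was seen in the sterile-medium library. CPM is
    recomputed on the retained total. Returns the new table and the
    count-weighted removed fraction; idempotent by construction.
    """
    medium = {s.upper() for s in medium_seqs}
    df = table.df
    keep = ~df["seq"].isin(medium)
    removed = int(df.loc[~keep, "count"].sum())
    total = int(df["count"].sum())
    out = cpm_normalize(AnnotatedCountTable(df[keep].reset_index(drop=True), 0))
    frac = removed / total if total else 0.0
    return out, frac


@dataclass
class LengthDistribution:
    """Summed normalized abundance per fragment length, 8-30 nt."""

    per_length: dict[int, float]
    vsrna_total: float  # 8-15 nt
    srna_total: float  # 16-30 nt

    @property
    def grand_total(self) -> float:
        return self.vsrna_total + self.srna_total


def length_profile(table: AnnotatedCountTable, value: str = "cpm") -> LengthDistribution:
    """Per-length abundance sums split at the 15/16 nt window boundary."""
    df = table.df
    sums = df.groupby("length")[value].sum()
    per_length = {int(l): float(v) for l, v in sums.items() if 8 <= l <= 30}
    vs = sum(v for l, v in per_length.items() if VSRNA_WINDOW[0] <= l <= VSRNA_WINDOW[1])
    sr = sum(v for l, v in per_length.items() if SRNA_WINDOW[0] <= l <= SRNA_WINDOW[1])
    return LengthDistribution(per_length, vs, sr)


def biotype_composition(
    table: AnnotatedCountTable, window: tuple[int, int] | None = None
) -> pd.Series:
    """Count-weighted biotype fractions, optionally within a length window."""
    df = table.df
    if window is not None:
        df = df[(df["length"] >= window[0]) & (df["length"] <= window[1])]
    total = df["count"].sum()
    if total == 0:
        return pd.Series(dtype=float)
    return (df.groupby("biotype")["count"].sum() / total).sort_index()


@dataclass
class LoadingComparison:
    """Per-length OMV/cell abundance ratios (selective-loading profile).

    ``ratio[L]`` is RPM_omv(L) / RPM_cell(L); lengths with zero cell signal
    are flagged undefined rather than imputed. ``log2_ratio`` is NaN where
    the ratio is 0 or undefined.
    """

    ratio: dict[int, float]
    log2_ratio: dict[int, float]
    undefined_lengths: list[int] = field(default_factory=list)


def loading_compare(
    cell: AnnotatedCountTable, omv: AnnotatedCountTable
) -> LoadingComparison:
    """Per-length RPM ratio profile between a cell library and its OMVs."""
    p_cell = length_profile(cell).per_length
    p_omv = length_profile(omv).per_length
    ratio: dict[int, float] = {}
    log2r: dict[int, float] = {}
    undefined: list[int] = []
    for L in sorted(set(p_cell) | set(p_omv)):
        c = p_cell.get(L, 0.0)
        o = p_omv.get(L, 0.0)
        if c == 0.0:
            undefined.append(L)
            continue
        r = o / c
        ratio[L] = r
        log2r[L] = math.log2(r) if r > 0 else float("nan")
    return LoadingComparison(ratio, log2r, undefined)


def top_n(table: AnnotatedCountTable, n: int = 20) -> pd.DataFrame:
    """The n most abundant sequences, ranked.

    Sorted by count descending; ties broken by sequence ascending so the
    ranking is total and reproducible. Columns: rank, count, seq, biotype,
    family ("possible origin").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = table.df.sort_values(
        ["count", "seq"], ascending=[False, True], kind="mergesort"
    ).head(n)
    df = df.reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df[["rank", "count", "seq", "biotype", "family", "cpm", "length"]]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def family_abundance(rows: pd.DataFrame, family: str, value: str = "count") -> float:
    """Summed abundance of one family's rows in a table extract."""
    return float(rows.loc[rows["family"] == family, value].sum())


def family_enrichment(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    family: str,
    value: str = "count",
) -> tuple[float, int]:
    """Fold-enrichment of a tRF family between two tables (B relative to A).

    Sums ``value`` over rows whose family matches, in each table; returns
    (raw ratio sumB/sumA, nearest-integer rounding). Raw counts are the
    right basis when the inputs are printed top-N extracts; CPM when full
    libraries are compared. Raises ValueError when the family is absent
    from A (undefined ratio).
    """
    sum_a = family_abundance(rows_a, family, value)
    sum_b = family_abundance(rows_b, family, value)
    if sum_a == 0:
        raise ValueError(f"family {family!r} has zero abundance in the denominator table")
    raw = sum_b / sum_a
    return raw, round_half_away(raw)
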