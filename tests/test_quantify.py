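"""CPM normalization, medium subtraction, profiles, top-N, fold-enrichment."""

import numpy as np
import pandas as pd
import pytest

from vsrna.datasets import load_top20
from vsrna.quantify import (
    AnnotatedCountTable,
    cpm_normalize,
    family_abundance,
    family_enrichment,
    length_profile,
    loading_compare,
    round_half_away,
    subtract_medium,
    top_n,
)


def _table(rows):
    """rows: (seq, count, biotype, family)"""
    return AnnotatedCountTable.from_rows(rows)


SIMPLE = [
    ("ACGTACGTAC", 3, "mRNA", "geneA"),
    ("GGGGCCCCAAA", 1, "tRNA", "tRNA-Ile"),
]


class TestCpm:
    def test_single_sequence_gets_the_whole_million(self):
        t = _table([("ACGTACGT", 5, "mRNA", "g")])
        assert t.df["cpm"].iloc[0] == pytest.approx(1e6)

    def test_three_to_one_split(self):
        t = _table(SIMPLE)
        assert sorted(t.df["cpm"]) == [pytest.approx(250_000), pytest.approx(750_000)]

    def test_cpm_sums_to_one_million(self):
        t = load_top20("omv", as_table=True)
        assert t.df["cpm"].sum() == pytest.approx(1e6, abs=1e-6)

    def test_empty_table_no_division(self):
        t = cpm_normalize(AnnotatedCountTable(
            pd.DataFrame(columns=["seq", "count", "cpm", "biotype", "family", "length"]), 0))
        assert len(t) == 0

    def test_counts_untouched(self):
        t = _table(SIMPLE)
        assert sorted(t.df["count"]) == [1, 3]


class TestSubtractMedium:
    def test_empty_medium_set_changes_nothing(self):
        t = _table(SIMPLE)
        out, frac = subtract_medium(t, set())
        assert frac == 0.0
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_removal_is_count_conservative(self):
        t = _table(SIMPLE)
        out, frac = subtract_medium(t, {"ACGTACGTAC"})
        removed = frac * t.df["count"].sum()
        assert removed + out.df["count"].sum() == t.df["count"].sum()
        assert frac == pytest.approx(0.75)

    def test_output_shares_no_sequence_with_medium(self):
        medium = {"ACGTACGTAC"}
        out, _ = subtract_medium(_table(SIMPLE), medium)
        assert not set(out.df["seq"]) & medium

    def test_idempotent(self):
        medium = {"ACGTACGTAC"}
        once, _ = subtract_medium(_table(SIMPLE), medium)
        twice, frac2 = subtract_medium(once, medium)
        assert frac2 == 0.0
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_cpm_renormalized_on_new_total(self):
        out, _ = subtract_medium(_table(SIMPLE), {"ACGTACGTAC"})
        assert out.df["cpm"].sum() == pytest.approx(1e6)


class TestLengthProfile:
    def test_all_mass_at_13(self):
        t = _table([("A" * 13, 4, "tRNA", "x"), ("C" * 13, 6, "tRNA", "y")])
        prof = length_profile(t)
        assert set(prof.per_length) == {13}
        assert prof.vsrna_total == pytest.approx(prof.grand_total)

    def test_uniform_counts_split_8_to_15_vs_16_to_30(self):
        t = _table([("A" * L, 1, "mRNA", "g") for L in range(8, 31)])
        prof = length_profile(t)
        per = set(np.round(list(prof.per_length.values()), 6))
        assert len(per) == 1  # equal mass per length
        assert prof.vsrna_total / prof.srna_total == pytest.approx(8 / 15)

    def test_window_totals_sum_to_grand_total(self):
        t = load_top20("cell", as_table=True)
        prof = length_profile(t)
        assert prof.vsrna_total + prof.srna_total == pytest.approx(1e6)


class TestLoadingCompare:
    def test_identical_tables_unit_ratio(self):
        t = _table(SIMPLE)
        comp = loading_compare(t, t)
        assert all(r == pytest.approx(1.0) for r in comp.ratio.values())

    def test_missing_length_in_omv_gives_zero(self):
        cell = _table([("A" * 10, 5, "mRNA", "g"), ("C" * 12, 5, "mRNA", "g")])
        omv = _table([("A" * 10, 5, "mRNA", "g")])
        comp = loading_compare(cell, omv)
        assert comp.ratio[12] == 0.0

    def test_zero_cell_length_flagged_not_imputed(self):
        cell = _table([("A" * 10, 5, "mRNA", "g")])
        omv = _table([("A" * 10, 5, "mRNA", "g"), ("C" * 12, 5, "mRNA", "g")])
        comp = loading_compare(cell, omv)
        assert 12 in comp.undefined_lengths and 12 not in comp.ratio

    def test_reciprocal_ratios_multiply_to_one(self):
        a = _table(SIMPLE)
        b = _table([(s, c * 2 + 1, bt, f) for s, c, bt, f in SIMPLE])
        ab = loading_compare(a, b)
        ba = loading_compare(b, a)
        for L in ab.ratio:
            assert ab.ratio[L] * ba.ratio[L] == pytest.approx(1.0)


class TestTopN:
    def test_shuffled_published_counts_reproduce_printed_order(self):
        df = load_top20("cell")
        shuffled = df.sample(frac=1, random_state=5)
        t = AnnotatedCountTable.from_rows(
            [(r.seq, r.count, "x", r.family) for r in shuffled.itertuples()]
        )
        ranked = top_n(t, 20)
        assert list(ranked["count"].head(3)) == [9295, 8150, 7776]
        assert list(ranked["seq"]) == list(df["seq"])

    def test_ties_broken_lexicographically(self):
        t = _table([("CCCCCCCC", 5, "x", "f"), ("AAAAAAAA", 5, "x", "f")])
        assert list(top_n(t, 2)["seq"]) == ["AAAAAAAA", "CCCCCCCC"]

    def test_n_larger_than_table(self):
        t = _table(SIMPLE)
        assert len(top_n(t, 100)) == 2

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_n(_table(SIMPLE), 0)


class TestFamilyEnrichment:
    def test_ala_trf_18_fold_omv_over_cell(self):
        raw, rounded = family_enrichment(load_top20("cell"), load_top20("omv"), "tRNA-Ala")
        assert raw == pytest.approx(46637 / 2611)
        assert rounded == 18

    def test_ile_trf_9_fold_omv_over_cell(self):
        raw, rounded = family_enrichment(load_top20("cell"), load_top20("omv"), "tRNA-Ile")
        assert raw == pytest.approx(180368 / 19721)
        assert rounded == 9

    def test_identical_tables_ratio_one(self):
        df = load_top20("cell")
        raw, rounded = family_enrichment(df, df, "tRNA-Ile")
        assert raw == 1.0 and rounded == 1

    def test_antisymmetry(self):
        fwd, _ = family_enrichment(load_top20("cell"), load_top20("omv"), "tRNA-Ala")
        rev, _ = family_enrichment(load_top20("omv"), load_top20("cell"), "tRNA-Ala")
        assert fwd * rev == pytest.approx(1.0)

    def test_absent_family_rejected(self):
        with pytest.raises(ValueError):
            family_enrichment(load_top20("cell"), load_top20("omv"), "tRNA-Pro")

    def test_family_abundance_sums(self):
        assert family_abundance(load_top20("omv"), "tRNA-Pro") == 6184 + 4278


@pytest.mark.parametrize(
    "x,expected",
    [(9.146, 9), (17.861, 18), (3.867, 4), (0.5, 1), (-0.5, -1), (2.5, 3), (7.55, 8)],
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
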