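"""Conserved windows, consensus, Tm, primer scoring and pairing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import spacerprime as sp
from spacerprime.design import (Alignment, column_identity, consensus,
                                enumerate_candidates, find_conserved_windows,
                                max_hairpin_run, max_self_dimer_run,
                                pair_primers, score_primer, tm)
from spacerprime.records import Primer


def aln(*rows):
    return Alignment([sp.SeqRecord(f"r{i}", s, aligned=True)
                      for i, s in enumerate(rows)])


class TestColumnIdentity:
    def test_unanimous_column(self):
        a = aln("GA", "GA", "GA")
        assert column_identity(a, 0) == 1.0

    def test_three_quarters(self):
        a = aln("A", "A", "A", "C")
        assert column_identity(a, 0) == 0.75

    def test_all_gaps_is_zero(self):
        a = aln("-A", "-A")
        assert column_identity(a, 0) == 0.0

    def test_gap_rows_excluded_from_denominator(self):
        a = aln("A", "A", "-", "-")
        assert column_identity(a, 0) == 1.0


class TestConservedWindows:
    def test_identical_rows_give_one_full_window(self):
        row = "ACGTAGGCTACCGGTTAACGGCTTACGATCGGATCCTAGGCATCGATCGGATTACGGATC"
        w = find_conserved_windows(aln(row, row, row))
        assert [(x.start, x.end) for x in w] == [(0, 60)]
        assert w[0].consensus == row

    def test_single_divergent_column_splits_window(self):
        row = "ACGTAGGCTACCGGTTAACGGCTTACGATCGGATCCTAGGCATCGATCGGATTACGGATC"
        rows = [row, row, row[:30] + "T" + row[31:], row[:30] + "G" + row[31:]]
        # column 30 identity 0.5 < 0.9 -> runs of 30 and 29
        w = find_conserved_windows(aln(*rows), min_len=15)
        assert [(x.start, x.end) for x in w] == [(0, 30), (31, 60)]

    def test_run_shorter_than_min_len_dropped(self):
        row = "ACGTAGGCTACCGG"  # 14 columns < 15
        assert find_conserved_windows(aln(row, row)) == []

    def test_no_conserved_column_gives_empty_list(self):
        a = aln("AAAA", "CCCC", "GGGG", "TTTT")
        assert find_conserved_windows(a) == []

    def test_windows_are_disjoint_and_maximal(self):
        row = "ACGTAGGCTACCGGTTAACGGCTTACGATCGGATCCTAGGCATCGATCGGATTACGGATC"
        rows = [row, row, row[:20] + "C" + row[21:], row[:45] + "A" + row[46:]]
        ws = find_conserved_windows(aln(*rows), min_len=5)
        for a_, b_ in zip(ws, ws[1:]):
            assert a_.end < b_.start  # disjoint, separated by a bad column


class TestConsensus:
    def test_identical_rows_return_that_row(self):
        a = aln("ACGT", "ACGT")
        assert consensus(a, "majority") == "ACGT"
        assert consensus(a, "iupac") == "ACGT"

    def test_even_split_gives_ambiguity_code(self):
        a = aln("C", "T")
        assert consensus(a, "iupac") == "Y"

    def test_minor_base_floor(self):
        rows = ["A"] * 9 + ["G"]
        assert consensus(aln(*rows), "iupac", threshold=0.1) == "R"
        assert consensus(aln(*rows), "iupac", threshold=0.2) == "A"

    def test_gap_majority_columns_dropped(self):
        a = aln("A-C", "A-C", "AT-")
        assert consensus(a, "majority") == "AC"


class TestTm:
    def test_wallace_at_count_formula(self):
        assert tm("AAAATTTT", "wallace") == 16.0  # 8 A/T bases, 2 degC each

    def test_wallace_606F(self, primers):
        assert tm(primers["606F"], "wallace") == 64.0  # 2*8 + 4*12

    def test_degenerate_takes_lowest_expansion(self, primers):
        # 1084R's Y resolves to T in the worst case: S->G/C would add 4
        p = primers["1084R"]
        variants = [tm(Primer("v", v, "reverse"), "wallace")
                    for v in sp.iupac.expand(p.seq)]
        assert tm(p, "wallace") == min(variants)

    def test_nn_within_8C_of_wallace_for_typical_primers(self, primers):
        for p in primers.values():
            assert abs(tm(p, "nn") - tm(p, "wallace")) <= 8.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tm("ACGTACG")


class TestScorePrimer:
    def test_606F_flags_three_prime_A(self, primers):
        s = score_primer(primers["606F"])
        assert s.three_prime_A is True

    def test_1082R_has_no_three_prime_A(self, primers):
        assert score_primer(primers["1082R"]).three_prime_A is False

    def test_all_gc_primer(self):
        s = score_primer(Primer("g", "GGGGGGGGGGGG", "forward"))
        assert s.gc == 1.0

    def test_palindromic_core_has_long_self_dimer_run(self):
        assert max_self_dimer_run("ACGAATTCGACT") >= 6  # GAATTC core

    def test_hairpin_run_found(self):
        # GGGGC...loop...GCCCC pairs a 5-stem with a 4-base loop
        assert max_hairpin_run("GGGGCTTTTGCCCC") >= 4

    def test_three_prime_A_penalty_lowers_composite(self):
        a = score_primer(Primer("a", "GTCGATGAAGAGCGCAGCCA", "forward"))
        b = score_primer(Primer("b", "GTCGATGAAGAGCGCAGCCG", "forward"))
        assert a.composite < b.composite


@pytest.fixture(scope="module")
def designed():
    """Deterministic gap-free panel (equal partition lengths) and its
    conserved windows."""
    ranges = {k: (v, v) for k, v in dict(
        tail18S_len=90, ITS1_len=450, ITS2_len=300, head28S_len=80).items()}
    panel = sp.make_panel(30, 0, spec_ranges=ranges, seed=11)
    a = Alignment([rec for rec, _ in panel])
    windows = find_conserved_windows(a)
    return a, windows


class TestPairing:
    def test_flanking_windows_pair_under_wide_bounds(self, designed):
        a, windows = designed
        fwd = enumerate_candidates(windows, "forward", 20)
        rev = enumerate_candidates(windows, "reverse", 21)
        ranked = pair_primers(fwd, rev, a.to_template_coords(), 200, 1250)
        assert ranked
        pair, _, product = ranked[0]
        assert 200 <= product <= 1250
        assert pair.fwd.orientation == "forward"
        assert pair.rev.orientation == "reverse"

    def test_product_below_min_len_excluded(self, designed):
        a, windows = designed
        fwd = enumerate_candidates(windows, "forward", 20)
        rev = enumerate_candidates(windows, "reverse", 21)
        # the ITS2-style product here is ~360-660 bp; a 700 bp floor kills
        # 5.8S->28S pairs, a 400 bp floor keeps them
        ok = pair_primers(fwd, rev, a.to_template_coords(), 400, 2500)
        none_short = pair_primers(fwd, rev, a.to_template_coords(), 700, 1250)
        assert ok
        products = [p for _, _, p in none_short]
        assert all(x >= 700 for x in products)

    def test_single_sided_candidates_pair_to_nothing(self, designed):
        a, windows = designed
        fwd = enumerate_candidates(windows[:1], "forward", 20)
        assert pair_primers(fwd, [], a.to_template_coords(), 200, 1250) == []

    def test_candidates_lie_inside_their_windows(self, designed):
        _, windows = designed
        for cand in enumerate_candidates(windows, "forward", 20):
            assert any(w.start <= cand.start and cand.end <= w.end
                       for w in windows)


@given(st.text(alphabet="ACGTRY", min_size=1, max_size=12),
       st.text(alphabet="ACGTRY", min_size=1, max_size=12))
def test_degeneracy_multiplicative_over_concatenation(a, b):
    assert sp.degeneracy(a + b) == sp.degeneracy(a) * sp.degeneracy(b)
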