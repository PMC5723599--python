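"""In silico PCR: mismatch counting, scanning, amplification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spacerprime as sp
from spacerprime.records import Primer, PrimerPair
from spacerprime.synth import CassetteSpec, make_cassette


def brute_force_exact_sites(primer_seq: str, template: str) -> set[tuple[str, int]]:
    """Independent oracle: expand all degenerate variants and use plain
    substring search on both strands."""
    sites = set()
    for strand, text in (("+", primer_seq),
                         ("-", sp.reverse_complement(primer_seq))):
        for variant in sp.iupac.expand(text):
            start = template.find(variant)
            while start != -1:
                sites.add((strand, start))
                start = template.find(variant, start + 1)
    return sites


def random_template(rng, n=300):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCountMismatches:
    def test_exact_site_is_zero(self, primers, cassette):
        rec, _, truth = cassette
        window = rec.sequence[truth.fwd_site[0]:truth.fwd_site[1]]
        assert sp.count_mismatches(primers["606F"], window) == (0, [])

    def test_planted_count_recovered(self, primers):
        rng = np.random.default_rng(5)
        p = primers["606F"]
        for k in (1, 2, 3, 5):
            window = sp.mutate_window(p.seq, (0, len(p.seq)), k, seed=int(rng.integers(1 << 30)))
            n, pos = sp.count_mismatches(p, window)
            assert n == len(pos) == k

    def test_length_mismatch_raises(self, primers):
        with pytest.raises(ValueError):
            sp.count_mismatches(primers["606F"], "ACGT")


class TestScanPrimer:
    def test_planted_exact_site(self, primers, cassette):
        rec, _, truth = cassette
        hits = sp.scan_primer(primers["606F"], rec, max_mm=0)
        assert [(h.start, h.end, h.strand, h.mismatches) for h in hits] == [
            (truth.fwd_site[0], truth.fwd_site[1], "+", 0)]

    def test_reverse_primer_found_on_minus_strand(self, primers, cassette):
        rec, _, truth = cassette
        hits = sp.scan_primer(primers["1082R"], rec, max_mm=0)
        assert [(h.start, h.strand) for h in hits] == [(truth.rev_site[0], "-")]

    def test_agrees_with_brute_force_at_zero_mismatches(self, primers):
        rng = np.random.default_rng(11)
        for primer in (primers["606F"], primers["1084R"]):
            for _ in range(40):
                tmpl = random_template(rng)
                # plant one exact copy so matches exist
                variant = next(sp.iupac.expand(primer.seq))
                pos = int(rng.integers(0, len(tmpl) - len(variant)))
                tmpl = tmpl[:pos] + variant + tmpl[pos + len(variant):]
                rec = sp.SeqRecord("t", tmpl)
                got = {(h.strand, h.start)
                       for h in sp.scan_primer(primer, rec, max_mm=0)}
                assert got == brute_force_exact_sites(primer.seq, tmpl)

    def test_hit_sets_monotone_in_budget(self, primers):
        rng = np.random.default_rng(13)
        p = primers["606F"]
        for _ in range(20):
            rec = sp.SeqRecord("t", random_template(rng))
            sets = [{(h.strand, h.start, h.mismatches)
                     for h in sp.scan_primer(p, rec, max_mm=k)}
                    for k in (4, 6, 8)]
            assert sets[0] <= sets[1] <= sets[2]


class TestAmplify:
    def test_planted_cassette_single_e0_amplicon(self, its2_pair, cassette):
        rec, _, truth = cassette
        hits = sp.amplify(its2_pair, rec, max_mm=3)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (truth.fwd_site[0], truth.rev_site[1])
        assert (h.insert_start, h.insert_end) == (truth.fwd_site[1], truth.rev_site[0])
        assert h.e_class == "e0" and h.strand == "+"

    def test_length_window_excludes_short_product(self, its2_pair, cassette):
        rec, _, _ = cassette
        narrow = PrimerPair(its2_pair.fwd, its2_pair.rev, min_len=400, max_len=2500)
        # the planted product is ~464 bp; shift the window above it
        tight = PrimerPair(its2_pair.fwd, its2_pair.rev, min_len=600, max_len=2500)
        assert len(sp.amplify(narrow, rec, max_mm=0)) == 1
        assert sp.amplify(tight, rec, max_mm=0) == []

    def test_e_class_is_max_of_per_primer_mismatches(self, its2_pair):
        rec, _, truth = make_cassette(CassetteSpec(seed=21, fwd_site_mm=0,
                                                   rev_site_mm=2))
        hits = sp.amplify(its2_pair, rec, max_mm=3)
        assert len(hits) == 1
        assert (hits[0].fwd_mm, hits[0].rev_mm) == (0, 2)
        assert hits[0].e_class == "e2"

    def test_monotone_in_budget_and_window(self, its2_pair):
        rec, _, _ = make_cassette(CassetteSpec(seed=33, fwd_site_mm=2, rev_site_mm=1))
        def key(h):
            return (h.start, h.end, h.strand)
        h1 = {key(h) for h in sp.amplify(its2_pair, rec, max_mm=1)}
        h2 = {key(h) for h in sp.amplify(its2_pair, rec, max_mm=2)}
        h3 = {key(h) for h in sp.amplify(its2_pair, rec, max_mm=3)}
        assert h1 <= h2 <= h3
        wide = PrimerPair(its2_pair.fwd, its2_pair.rev, min_len=1, max_len=10_000)
        h_wide = {key(h) for h in sp.amplify(wide, rec, max_mm=3)}
        assert h3 <= h_wide

    def test_mirror_symmetry_under_reverse_complement(self, its2_pair):
        rec, _, _ = make_cassette(CassetteSpec(seed=44, fwd_site_mm=1, rev_site_mm=1))
        n = len(rec.sequence)
        flipped = sp.SeqRecord(rec.id, sp.reverse_complement(rec.sequence))
        fwd_hits = sp.amplify(its2_pair, rec, max_mm=3)
        rev_hits = sp.amplify(its2_pair, flipped, max_mm=3)
        mirrored = {(n - h.end, n - h.start, h.fwd_mm, h.rev_mm,
                     "-" if h.strand == "+" else "+") for h in fwd_hits}
        got = {(h.start, h.end, h.fwd_mm, h.rev_mm, h.strand) for h in rev_hits}
        assert got == mirrored


class TestRunDatabase:
    def test_empty_database(self, its2_pair):
        assert sp.run_database(its2_pair, []) == []

    def test_only_targets_amplify(self, its2_pair, small_panel):
        db = [rec for rec, _ in small_panel]
        hits = sp.run_database(its2_pair, db, max_mm=3)
        amplified = {h.template_id for h in hits}
        assert amplified == {r.id for r in db if r.is_target}
        assert len(amplified) == 10

    def test_duplicate_record_duplicates_hits(self, its2_pair, cassette):
        rec, _, _ = cassette
        hits = sp.run_database(its2_pair, [rec, rec], max_mm=0)
        assert len(hits) == 2 and hits[0] == hits[1]

    def test_best_per_template_prefers_lowest_e_class(self, its2_pair):
        a = sp.AmpliconHit("t", "p", 10, 300, 30, 280, fwd_mm=2, rev_mm=0)
        b = sp.AmpliconHit("t", "p", 12, 300, 32, 280, fwd_mm=0, rev_mm=1)
        assert sp.best_per_template([a, b]) == [b]
        assert sp.best_per_template([b]) == [b]  # idempotent


@given(st.integers(min_value=0, max_value=3), st.integers(min_value=0, max_value=3))
def test_planted_mismatch_counts_surface_in_e_class(fmm, rmm):
    pair = sp.its2_pair()
    rec, _, truth = make_cassette(CassetteSpec(seed=100 + 7 * fmm + rmm,
                                               fwd_site_mm=fmm, rev_site_mm=rmm))
    hits = sp.amplify(pair, rec, max_mm=3)
    assert len(hits) == 1
    assert (hits[0].fwd_mm, hits[0].rev_mm) == (fmm, rmm)
    assert hits[0].e_index == max(fmm, rmm)
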