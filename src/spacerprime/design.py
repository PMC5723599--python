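"""Conserved-window discovery and primer candidate design on an alignment.

The workflow mirrors classic conserved-site primer design: compute
per-column identity on a multiple sequence alignment, keep maximal runs of
highly conserved, gap-poor columns at least 15 columns long (">14
nucleotides"), take the window consensus as a (possibly degenerate)
candidate source, score candidates, and pair forward/reverse candidates
under a product-length window and a melting-temperature balance constraint.

The composite score is a documented heuristic - commercial design tools do
not publish theirs - and all weights are exposed on :class:`ScoreParams`.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from . import iupac
from .records import Primer, PrimerPair, SeqRecord

log = logging.getLogger(__name__)

_CODE_BY_MASK = {m: s for s, m in iupac.MASKS.items() if s != "-"}


@dataclass
class Alignment:
    """A gapped multiple sequence alignment (rows of equal length)."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def column(self, col: int) -> str:
        return "".join(r.sequence[col] for r in self.records)

    def to_template_coords(self) -> list[int]:
        """Median (over rows) ungapped coordinate of each alignment column:
        the number of non-gap characters strictly before the column."""
        per_row = []
        for r in self.records:
            acc, coords = 0, []
            for ch in r.sequence:
                coords.append(acc)
                if ch != "-":
                    acc += 1
            per_row.append(coords)
        return [int(statistics.median(row[c] for row in per_row))
                for c in range(self.length)]


@dataclass(frozen=True)
class ConservedWindow:
    """A maximal run of conserved alignment columns."""

    start: int
    end: int
    consensus: str
    min_column_identity: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerScore:
    tm: float
    gc: float
    degeneracy: int
    max_hairpin_run: int
    max_self_dimer_run: int
    three_prime_A: bool
    composite: float


@dataclass
class ScoreParams:
    """Weights and caps of the composite primer score (higher is better).

    The score starts at 100 and subtracts documented penalties; defaults
    reward 40-60% GC, Tm near 60 degC, low degeneracy, short
    self-complementary runs, and a non-A 3' terminus (a 3'-terminal A is
    reported to extend poorly with Taq polymerase).
    """

    tm_target: float = 60.0
    tm_weight: float = 1.0
    gc_lo: float = 0.40
    gc_hi: float = 0.60
    gc_weight: float = 50.0
    degeneracy_cap: int = 8
    degeneracy_weight: float = 5.0
    hairpin_cap: int = 4
    dimer_cap: int = 6
    run_weight: float = 3.0
    three_prime_A_penalty: float = 10.0
    max_dTm: float = 8.0


def column_identity(aln: Alignment, col: int) -> float:
    """Frequency of the modal non-gap base among non-gap rows of a column;
    a column of only gaps has identity 0."""
    bases = [b for b in aln.column(col) if b != "-"]
    if not bases:
        return 0.0
    return Counter(bases).most_common(1)[0][1] / len(bases)


def column_gap_fraction(aln: Alignment, col: int) -> float:
    colstr = aln.column(col)
    return colstr.count("-") / len(colstr)


def consensus(aln: Alignment, mode: str = "iupac", threshold: float = 0.1) -> str:
    """Column-wise consensus of an alignment.

    ``majority`` emits the modal non-gap base per column (alphabetic
    tiebreak); ``iupac`` emits the smallest IUPAC code covering every base
    whose non-gap frequency is at least *threshold* (the minor-base floor).
    Columns where gaps are the majority are dropped.
    """
    if mode not in ("majority", "iupac"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    out = []
    for col in range(aln.length):
        colstr = aln.column(col)
        if colstr.count("-") * 2 > len(colstr):
            continue
        counts = Counter()
        for sym in colstr:
            if sym == "-":
                continue
            bases = iupac.SETS[sym]
            for b in bases:  # ambiguity codes spread fractionally
                counts[b] += 1.0 / len(bases)
        total = sum(counts.values())
        if total == 0:
            continue
        if mode == "majority":
            out.append(max(sorted(counts), key=lambda b: counts[b]))
        else:
            kept = [b for b in "ACGT" if counts.get(b, 0.0) / total >= threshold]
            if not kept:
                kept = [max(sorted(counts), key=lambda b: counts[b])]
            mask = 0
            for b in kept:
                mask |= iupac.MASKS[b]
            out.append(_CODE_BY_MASK[mask])
    return "".join(out)


def find_conserved_windows(aln: Alignment, min_len: int = 15,
                           min_identity: float = 0.90,
                           max_gap_fraction: float = 0.10,
                           ) -> list[ConservedWindow]:
    """Maximal runs of >= *min_len* consecutive columns with identity >=
    *min_identity* and gap fraction <= *max_gap_fraction*, sorted by start.
    Windows are disjoint and not extendable by construction."""
    good = [
        column_identity(aln, c) >= min_identity
        and column_gap_fraction(aln, c) <= max_gap_fraction
        for c in range(aln.length)
    ]
    windows = []
    col = 0
    while col < aln.length:
        if not good[col]:
            col += 1
            continue
        run_start = col
        while col < aln.length and good[col]:
            col += 1
        if col - run_start >= min_len:
            sub = Alignment([SeqRecord(r.id, r.sequence[run_start:col], aligned=True)
                             for r in aln.records])
            windows.append(ConservedWindow(
                start=run_start, end=col,
                consensus=consensus(sub, mode="iupac"),
                min_column_identity=min(column_identity(aln, c)
                                        for c in range(run_start, col))))
    return windows


def degeneracy(p: Primer | str) -> int:
    """Product over positions of IUPAC set sizes."""
    return iupac.degeneracy(p.seq if isinstance(p, Primer) else p)


def tm(p: Primer | str, method: str = "wallace") -> float:
    """Melting temperature in degC; for degenerate primers, the lowest-Tm
    unambiguous expansion (the worst-case variant of the mixture).

    ``wallace``: 2(A+T) + 4(G+C).  ``nn``: nearest-neighbor (SantaLucia
    unified parameters as implemented in Biopython) under PCR-typical
    conditions: 250 nM primer, 50 mM monovalent salt, 1.5 mM Mg2+ with the
    Owczarzy magnesium correction.
    """
    seq = p.seq if isinstance(p, Primer) else iupac.validate(p)
    if len(seq) < 8:
        raise ValueError(f"primer too short for a Tm estimate: {len(seq)} nt")
    if method == "wallace":
        # per-position minimum: A/T contribute 2, G/C contribute 4
        return float(sum(
            min(2 if b in "AT" else 4 for b in iupac.SETS[ch]) for ch in seq))
    if method == "nn":
        return min(float(_mt.Tm_NN(variant, dnac1=250, dnac2=0, Na=50, Mg=1.5,
                           saltcorr=7))
                   for variant in iupac.expand(seq, cap=64))
    raise ValueError(f"unknown Tm method {method!r}")


def _max_complementary_run(a: str, b: str) -> int:
    """Longest stretch where a[i..i+k] pairs with the reverse complement of
    an equal-length stretch of *b* (IUPAC-aware), over all offsets."""
    rb = iupac.reverse_complement(b)
    best = 0
    for i in range(len(a)):
        for j in range(len(rb)):
            k = 0
            while (i + k < len(a) and j + k < len(rb)
                   and iupac.MASKS[a[i + k]] & iupac.MASKS[rb[j + k]]):
                k += 1
            best = max(best, k)
    return best


def max_self_dimer_run(seq: str) -> int:
    """Longest self-complementary stretch (primer-dimer propensity)."""
    return _max_complementary_run(seq, seq)


def max_hairpin_run(seq: str, min_loop: int = 3) -> int:
    """Longest intramolecular stem closable with a loop of >= *min_loop*."""
    best = 0
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n):
            k = 0
            # stem pairs (i+k, j-k); the unpaired loop between them must
            # keep at least min_loop bases: (j-k) - (i+k) - 1 >= min_loop
            while ((j - k) - (i + k) - 1 >= min_loop
                   and iupac.MASKS[seq[i + k]]
                   & iupac.MASKS[iupac.reverse_complement(seq[j - k])]):
                k += 1
            best = max(best, k)
    return best


def score_primer(p: Primer, params: ScoreParams | None = None) -> PrimerScore:
    """Populate every score field and the composite (see ScoreParams)."""
    prm = params or ScoreParams()
    seq = p.seq
    gc = sum(1 for ch in seq if set(iupac.SETS[ch]) <= {"G", "C"}) / len(seq)
    deg = iupac.degeneracy(seq)
    hairpin = max_hairpin_run(seq)
    dimer = max_self_dimer_run(seq)
    three_a = seq[-1] in ("A", "W", "M", "R")  # 3' terminus can be an A
    t = tm(p, "wallace")

    composite = 100.0
    composite -= prm.tm_weight * abs(t - prm.tm_target)
    if gc < prm.gc_lo:
        composite -= prm.gc_weight * (prm.gc_lo - gc)
    elif gc > prm.gc_hi:
        composite -= prm.gc_weight * (gc - prm.gc_hi)
    if deg > prm.degeneracy_cap:
        composite -= prm.degeneracy_weight * (deg - prm.degeneracy_cap)
    if hairpin > prm.hairpin_cap:
        composite -= prm.run_weight * (hairpin - prm.hairpin_cap)
    if dimer > prm.dimer_cap:
        composite -= prm.run_weight * (dimer - prm.dimer_cap)
    if three_a:
        composite -= prm.three_prime_A_penalty
    return PrimerScore(tm=t, gc=gc, degeneracy=deg, max_hairpin_run=hairpin,
                       max_self_dimer_run=dimer, three_prime_A=three_a,
                       composite=composite)


@dataclass(frozen=True)
class Candidate:
    """A primer candidate anchored to alignment columns [start, end)."""

    primer: Primer
    start: int
    end: int
    score: PrimerScore


def enumerate_candidates(windows: list[ConservedWindow], orientation: str,
                         primer_len: int = 20,
                         params: ScoreParams | None = None,
                         degeneracy_cap: int = 8) -> list[Candidate]:
    """Slide a *primer_len* window over each conserved-window consensus.

    Forward candidates read the consensus as-is; reverse candidates are the
    reverse complement.  Names follow the positional convention used for
    rDNA primers ("<start+1>F" / "<end>R").  Candidates above the
    degeneracy cap are skipped.
    """
    out = []
    for w in windows:
        cons = w.consensus
        if len(cons) != len(w):  # gap columns were dropped; coords would drift
            log.debug("window %d-%d consensus shrank; skipping", w.start, w.end)
            continue
        for off in range(0, len(cons) - primer_len + 1):
            seq = cons[off : off + primer_len]
            if iupac.degeneracy(seq) > degeneracy_cap:
                continue
            a_start, a_end = w.start + off, w.start + off + primer_len
            if orientation == "forward":
                primer = Primer(f"{a_start + 1}F", seq, "forward")
            else:
                primer = Primer(f"{a_end}R", iupac.reverse_complement(seq), "reverse")
            out.append(Candidate(primer, a_start, a_end, score_primer(primer, params)))
    return out


def pair_primers(fwd_candidates: list[Candidate], rev_candidates: list[Candidate],
                 template_coords: list[int], min_len: int, max_len: int,
                 max_dTm: float = 8.0,
                 ) -> list[tuple[PrimerPair, float, int]]:
    """All pairs whose median product length (primer-inclusive, via the
    alignment-to-template coordinate map) lies in [min_len, max_len] and
    whose Wallace Tm difference is <= max_dTm, ranked by combined composite
    score, then shorter product, then name.

    Returns (pair, combined_score, product_length) tuples; an empty list
    (with a diagnostic log record) when nothing is feasible.
    """
    ranked = []
    for f in fwd_candidates:
        for r in rev_candidates:
            if r.start < f.end:
                continue
            product = template_coords[r.end - 1] + 1 - template_coords[f.start]
            if not (min_len <= product <= max_len):
                continue
            if abs(f.score.tm - r.score.tm) > max_dTm:
                continue
            pair = PrimerPair(f.primer, r.primer, min_len=min_len, max_len=max_len)
            ranked.append((pair, f.score.composite + r.score.composite, product))
    if not ranked:
        log.warning("no feasible primer pair under [%d, %d] bp, dTm <= %.1f",
                    min_len, max_len, max_dTm)
        return []
    ranked.sort(key=lambda t: (-t[1], t[2], t[0].name))
    return ranked
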