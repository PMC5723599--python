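"""Mismatch-tolerant in silico PCR (ecoPCR-style).

A primer anneals wherever the number of IUPAC-set mismatches against the
template window is within the budget; a pair amplifies wherever a forward
site and a downstream reverse site enclose a product whose primer-inclusive
length falls in the pair's window.  Each amplicon is classed e0-e3 by the
*maximum* per-primer mismatch count, following the usual reporting
convention for primer-coverage evaluations.

Matching is position-blind: a 3'-terminal mismatch counts the same as any
other (the 3'-A effect is handled at design-scoring time instead), and
template ambiguity codes participate in set-intersection matching
symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import iupac
from .records import Primer, PrimerPair, SeqRecord

# re-exported convenience
base_match = iupac.base_match
reverse_complement = iupac.reverse_complement


@dataclass(frozen=True)
class PrimerHit:
    """One annealing site of a single primer on a template."""

    template_id: str
    strand: str  # '+' : primer text on the sense strand; '-' : its complement
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.mismatch_positions and len(self.mismatch_positions) != self.mismatches:
            raise ValueError("mismatch count disagrees with positions")


@dataclass(frozen=True)
class AmpliconHit:
    """One in silico amplification event (sense-strand coordinates,
    primer-inclusive start/end, insert in between)."""

    template_id: str
    pair_name: str
    start: int
    end: int
    insert_start: int
    insert_end: int
    fwd_mm: int
    rev_mm: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def e_index(self) -> int:
        return max(self.fwd_mm, self.rev_mm)

    @property
    def e_class(self) -> str:
        return f"e{self.e_index}"


def count_mismatches(primer: Primer, window: str) -> tuple[int, list[int]]:
    """Mismatch count and primer-relative mismatch positions of *primer*
    laid 5'->3' over a same-length template *window*."""
    w = iupac.validate(window, allow_gaps=True)
    if len(w) != len(primer.seq):
        raise ValueError(f"window length {len(w)} != primer length {len(primer.seq)}")
    positions = [
        i for i, (p, t) in enumerate(zip(primer.seq, w))
        if not iupac.MASKS[p] & iupac.MASKS[t]
    ]
    return len(positions), positions


def _mismatch_vector(pmasks: np.ndarray, tmasks: np.ndarray) -> np.ndarray:
    """Per-start-position mismatch counts of a primer mask array slid along
    a template mask array."""
    L, n = pmasks.size, tmasks.size
    if n < L:
        return np.empty(0, dtype=np.int16)
    mm = np.zeros(n - L + 1, dtype=np.int16)
    for j in range(L):
        mm += (tmasks[j : n - L + 1 + j] & pmasks[j]) == 0
    return mm


def _sites(seq_masks: np.ndarray, primer_seq: str, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every window within budget."""
    mm = _mismatch_vector(iupac.encode(primer_seq), seq_masks)
    starts = np.nonzero(mm <= max_mm)[0]
    return [(int(s), int(mm[s])) for s in starts]


def find_motif(sequence: str, motif: str, max_mm: int = 0) -> list[tuple[int, int]]:
    """(start, mismatches) of every occurrence of an IUPAC motif on the
    given strand of *sequence* within the mismatch budget, left to right."""
    return _sites(iupac.encode(iupac.validate(sequence, allow_gaps=True)),
                  iupac.validate(motif), max_mm)


def scan_primer(primer: Primer, template: SeqRecord, max_mm: int = 0) -> list[PrimerHit]:
    """All annealing sites of *primer* on both strands of *template* with at
    most *max_mm* mismatches.  Overlapping sites are all reported.

    '+' hits are windows matching the primer text itself; '-' hits are
    windows matching its reverse complement (i.e. the primer anneals to the
    sense strand and extends leftwards).  ``mismatch_positions`` are always
    primer-relative (5'->3' along the primer).
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    tmasks = iupac.encode(template.sequence)
    L = len(primer.seq)
    hits: list[PrimerHit] = []
    for strand, text in (("+", primer.seq), ("-", iupac.reverse_complement(primer.seq))):
        for start, n_mm in _sites(tmasks, text, max_mm):
            window = template.sequence[start : start + L]
            pos = [i for i, (p, t) in enumerate(zip(text, window))
                   if not iupac.MASKS[p] & iupac.MASKS[t]]
            if strand == "-":
                pos = [L - 1 - p for p in pos]
            hits.append(PrimerHit(template.id, strand, start, start + L,
                                  n_mm, tuple(sorted(pos))))
    hits.sort(key=lambda h: (h.start, h.strand, h.mismatches))
    return hits


def amplify(pair: PrimerPair, template: SeqRecord, max_mm: int = 3) -> list[AmpliconHit]:
    """All amplicons of *pair* on *template* within the pair's length window.

    Both pair orientations are scanned: on the '+' strand the forward-primer
    text is followed downstream by the reverse complement of the reverse
    primer; the '-' strand is the mirror arrangement (products read off the
    antisense strand).  Every qualifying forward/reverse site combination is
    emitted - nested and overlapping amplicons are not collapsed (use
    :func:`best_per_template` for per-sequence counting).
    """
    tmasks = iupac.encode(template.sequence)
    f, r = pair.fwd.seq, pair.rev.seq
    out: list[AmpliconHit] = []

    def _emit(left_sites, right_sites, left_len, right_len, strand):
        for ls, lmm in left_sites:
            for rs, rmm in right_sites:
                if rs < ls + left_len:
                    continue
                length = rs + right_len - ls
                if pair.min_len <= length <= pair.max_len:
                    fwd_mm, rev_mm = (lmm, rmm) if strand == "+" else (rmm, lmm)
                    out.append(AmpliconHit(
                        template_id=template.id, pair_name=pair.name,
                        start=ls, end=rs + right_len,
                        insert_start=ls + left_len, insert_end=rs,
                        fwd_mm=fwd_mm, rev_mm=rev_mm, strand=strand))

    _emit(_sites(tmasks, f, max_mm),
          _sites(tmasks, iupac.reverse_complement(r), max_mm),
          len(f), len(r), "+")
    _emit(_sites(tmasks, r, max_mm),
          _sites(tmasks, iupac.reverse_complement(f), max_mm),
          len(r), len(f), "-")
    out.sort(key=lambda h: (h.start, h.end, h.strand))
    return out


def run_database(pairs: Sequence[PrimerPair] | PrimerPair,
                 db: Sequence[SeqRecord], max_mm: int = 3) -> list[AmpliconHit]:
    """Amplify every pair against every record; deterministic ordering
    (template order, then coordinates, then pair name).  Duplicate records
    yield duplicate hits - no deduplication."""
    if isinstance(pairs, PrimerPair):
        pairs = [pairs]
    hits: list[AmpliconHit] = []
    for rec in db:
        per_rec: list[AmpliconHit] = []
        for pair in pairs:
            per_rec.extend(amplify(pair, rec, max_mm))
        per_rec.sort(key=lambda h: (h.start, h.end, h.pair_name, h.strand))
        hits.extend(per_rec)
    return hits


def best_per_template(hits: Iterable[AmpliconHit]) -> list[AmpliconHit]:
    """Collapse to each (template, pair)'s best amplicon: lowest e-class,
    then leftmost, then shortest.  Preserves first-seen template order."""
    best: dict[tuple[str, str], AmpliconHit] = {}
    order: list[tuple[str, str]] = []
    for h in hits:
        key = (h.template_id, h.pair_name)
        cur = best.get(key)
        if cur is None:
            best[key] = h
            order.append(key)
        elif (h.e_index, h.start, h.length) < (cur.e_index, cur.start, cur.length):
            best[key] = h
    return [best[k] for k in order]
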