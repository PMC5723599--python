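"""IUPAC nucleotide alphabet primitives.

Every symbol is represented internally as a 4-bit mask over {A, C, G, T};
two symbols *match* iff their masks intersect.  This is the matching rule
used throughout the in silico PCR scan: a primer ``Y`` matches a template
``C`` or ``T``, and an ``N`` on either side matches anything.  The gap
character ``-`` carries an empty mask and therefore never matches.
"""

from __future__ import annotations

from itertools import product
from typing import Iterator

import numpy as np
from Bio.Seq import reverse_complement as _bio_revcomp

#: bit per base: A=1, C=2, G=4, T=8
MASKS: dict[str, int] = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b0000,
}

#: base set represented by each symbol
SETS: dict[str, str] = {
    sym: "".join(b for b, m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)) if mask & m)
    for sym, mask in MASKS.items()
}

ALPHABET = frozenset(MASKS)
UNAMBIGUOUS = frozenset("ACGT")

_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _mask in MASKS.items():
    _LUT[ord(_sym)] = _mask
    _LUT[ord(_sym.lower())] = _mask
# RNA input is accepted and treated as DNA
_LUT[ord("U")] = MASKS["T"]
_LUT[ord("u")] = MASKS["T"]


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the IUPAC DNA alphabet."""


def validate(seq: str, *, allow_gaps: bool = False) -> str:
    """Upper-case *seq*, convert U->T, and reject illegal symbols.

    Returns the normalized sequence.  Raises :class:`AlphabetError` naming
    the first offending symbol and its 0-based position.
    """
    norm = seq.upper().replace("U", "T")
    legal = ALPHABET if allow_gaps else ALPHABET - {"-"}
    for i, ch in enumerate(norm):
        if ch not in legal:
            raise AlphabetError(f"illegal symbol {ch!r} at position {i}")
    return norm


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of 4-bit base masks."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def base_match(primer_base: str, template_base: str) -> bool:
    """True iff the two IUPAC base sets intersect."""
    try:
        return bool(MASKS[primer_base.upper()] & MASKS[template_base.upper()])
    except KeyError as exc:  # pragma: no cover - defensive
        raise AlphabetError(f"illegal symbol {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (Y<->R, K<->M, B<->V, D<->H, N<->N)."""
    return str(_bio_revcomp(validate(seq, allow_gaps=True)))


def degeneracy(seq: str) -> int:
    """Product over positions of IUPAC set sizes (gaps are illegal)."""
    d = 1
    for ch in validate(seq):
        d *= len(SETS[ch])
    return d


def expand(seq: str, cap: int = 4096) -> Iterator[str]:
    """Yield every unambiguous ACGT expansion of a degenerate sequence.

    Raises ``ValueError`` if the number of expansions exceeds *cap*.
    """
    norm = validate(seq)
    if degeneracy(norm) > cap:
        raise ValueError(f"degeneracy of {seq!r} exceeds cap {cap}")
    for combo in product(*(SETS[ch] for ch in norm)):
        yield "".join(combo)


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases only; ambiguity codes are excluded
    from both numerator and denominator.  Returns 0.0 for sequences with no
    unambiguous base."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
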