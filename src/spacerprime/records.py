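"""Shared domain types: sequences, primers, primer pairs, specimens.

Coordinates everywhere in the package are 0-based, half-open, so that
``length == end - start`` without off-by-one bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import iupac


@dataclass
class SeqRecord:
    """One rDNA cassette (or any DNA sequence) plus taxonomy labels.

    ``is_target`` marks membership of the focal clade (here Clitellata) for
    specificity bookkeeping; off-target database entries carry ``False``.
    """

    id: str
    sequence: str
    family: str = ""
    species: str = ""
    is_target: bool = False
    aligned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = iupac.validate(self.sequence, allow_gaps=self.aligned)

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class Primer:
    """A 5'->3' oligo, possibly degenerate (IUPAC ambiguity codes)."""

    name: str
    seq: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        self.seq = iupac.validate(self.seq)
        if len(self.seq) < 12:
            raise ValueError(f"primer {self.name!r}: length {len(self.seq)} < 12")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: unknown orientation {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.seq)


@dataclass
class PrimerPair:
    """A forward/reverse primer pair with a product-length window (bp,
    primer-inclusive)."""

    fwd: Primer
    rev: Primer
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.fwd.orientation != "forward":
            raise ValueError(f"{self.fwd.name!r} is not a forward primer")
        if self.rev.orientation != "reverse":
            raise ValueError(f"{self.rev.name!r} is not a reverse primer")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"bad length window [{self.min_len}, {self.max_len}]")

    @property
    def name(self) -> str:
        return f"{self.fwd.name}/{self.rev.name}"


#: legal amplification-status tokens (paper-style "+", "-", "+/-")
STATUS_TOKENS = ("+", "-", "+/-")


def normalize_status(token: str) -> str:
    """Map the typographic minus (U+2212) used in the printed table onto
    ASCII and validate the token."""
    tok = token.strip().replace("−", "-")
    if tok not in STATUS_TOKENS:
        raise ValueError(f"unknown amplification status {token!r}")
    return tok


@dataclass
class SpecimenRecord:
    """One voucher specimen row: taxonomy, accession, and whether the whole
    ITS (29F/1084R) and the ITS2 (606F/1082R) amplifications succeeded."""

    specimen_id: str
    family: str
    species: str
    accession: str = ""
    amplified_its: str = "-"
    amplified_its2: str = "-"

    def __post_init__(self) -> None:
        self.amplified_its = normalize_status(self.amplified_its)
        self.amplified_its2 = normalize_status(self.amplified_its2)

    @property
    def genus(self) -> str:
        return self.species.split()[0] if self.species else ""
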