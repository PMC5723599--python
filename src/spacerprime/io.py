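"""Reading and writing the formats the toolkit touches.

FASTA goes through Biopython's SeqIO; tables are plain TSV via pandas.
Packaged fixtures (the four new ITS primers, the specimen table transcribed
from the in vitro verification study, and the synthetic 153-bp 5.8S
reference) are loaded with :mod:`importlib.resources`.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import iupac
from .records import Primer, PrimerPair, SeqRecord, SpecimenRecord


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def _offending_line(path, bad_char: str) -> int:
    """1-based line number of the first occurrence of *bad_char* in a
    sequence line (best effort, for error messages only)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(">") and bad_char in line.upper():
                return lineno
    return 0


def read_fasta(path, *, aligned: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequences are upper-cased, U is converted to T, and order is preserved.
    Symbols outside the IUPAC DNA alphabet raise :class:`ParseError` naming
    the line number; '-' is legal only when *aligned* is true.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first and not first.startswith(">"):
        raise ParseError(f"{path}:1: expected FASTA header starting with '>'")
    out: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(SeqRecord(id=rec.id, sequence=str(rec.seq), aligned=aligned))
        except iupac.AlphabetError as exc:
            bad = str(exc).split("'")[1]
            lineno = _offending_line(path, bad)
            raise ParseError(f"{path}:{lineno}: {exc} in record {rec.id!r}") from None
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return out


def write_fasta(path, records: Iterable[SeqRecord], *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# primer tables

def read_primer_table(path) -> list[Primer]:
    """Read a TSV with columns name, seq, orientation into Primer objects."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"name", "seq", "orientation"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    primers = []
    for row in df.itertuples(index=False):
        try:
            primers.append(Primer(row.name, row.seq, row.orientation))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return primers


def write_primer_table(path, primers: Iterable[Primer]) -> None:
    pd.DataFrame(
        [(p.name, p.seq, p.orientation) for p in primers],
        columns=["name", "seq", "orientation"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# specimen tables

_SPECIMEN_COLS = ["specimen_id", "family", "species",
                  "accession", "amplified_its", "amplified_its2"]


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read a specimen/taxonomy TSV (at minimum the SpecimenRecord columns).

    Order is preserved; a duplicated specimen_id is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = set(_SPECIMEN_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dupes.empty:
        raise ParseError(f"{path}: duplicate specimen_id {dupes.iloc[0]!r}")
    return [
        SpecimenRecord(*(getattr(row, c) for c in _SPECIMEN_COLS))
        for row in df.itertuples(index=False)
    ]


def taxon_tallies(specimens: Sequence[SpecimenRecord]) -> dict[str, int]:
    """Specimen, family and genus counts over a specimen table."""
    return {
        "specimens": len(specimens),
        "families": len({s.family for s in specimens if s.family}),
        "genera": len({s.genus for s in specimens if s.genus}),
    }


# ---------------------------------------------------------------------------
# amplicons

def amplicon_id(hit) -> str:
    """'<templateID>:<start>-<end>:<pairName>' - unique for multi-hit
    templates."""
    return f"{hit.template_id}:{hit.start}-{hit.end}:{hit.pair_name}"


_HIT_COLS = ["template_id", "pair", "strand", "start", "end",
             "insert_start", "insert_end", "length", "fwd_mm", "rev_mm", "e_class"]


def write_amplicons(fasta_path, tsv_path, hits, db: Sequence[SeqRecord]) -> None:
    """Write amplicon sequences as FASTA plus a TSV sidecar of coordinates
    and mismatch counts.  Rerunning on the same input is byte-identical."""
    by_id = {rec.id: rec for rec in db}
    seqs = []
    rows = []
    for h in hits:
        tmpl = by_id.get(h.template_id)
        if tmpl is None:
            raise KeyError(f"hit references unknown template {h.template_id!r}")
        seqs.append(SeqRecord(id=amplicon_id(h), sequence=tmpl.sequence[h.start : h.end]))
        rows.append((h.template_id, h.pair_name, h.strand, h.start, h.end,
                     h.insert_start, h.insert_end, h.end - h.start,
                     h.fwd_mm, h.rev_mm, h.e_class))
    write_fasta(fasta_path, seqs)
    pd.DataFrame(rows, columns=_HIT_COLS).to_csv(tsv_path, sep="\t", index=False)


def read_amplicon_table(path):
    """Read back an amplicon TSV sidecar into AmpliconHit objects."""
    from .pcr import AmpliconHit

    df = pd.read_csv(path, sep="\t")
    return [
        AmpliconHit(
            template_id=str(r.template_id), pair_name=str(r.pair),
            strand=str(r.strand), start=int(r.start), end=int(r.end),
            insert_start=int(r.insert_start), insert_end=int(r.insert_end),
            fwd_mm=int(r.fwd_mm), rev_mm=int(r.rev_mm),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# packaged fixtures

_DATA = files("spacerprime") / "data"


def load_its_primers() -> dict[str, Primer]:
    """The four clitellate ITS primers (29F, 1084R, 606F, 1082R) keyed by
    name."""
    with (_DATA / "primers_its.tsv").open() as fh:
        return {p.name: p for p in read_primer_table(fh)}


def its_pair() -> PrimerPair:
    """29F/1084R: whole-ITS pair, 400-2500 bp window."""
    p = load_its_primers()
    return PrimerPair(p["29F"], p["1084R"], min_len=400, max_len=2500)


def its2_pair() -> PrimerPair:
    """606F/1082R: ITS2 pair, 200-1250 bp window."""
    p = load_its_primers()
    return PrimerPair(p["606F"], p["1082R"], min_len=200, max_len=1250)


def load_specimen_table() -> list[SpecimenRecord]:
    """The packaged 71-specimen verification panel (11 families)."""
    with (_DATA / "table2_specimens.tsv").open() as fh:
        return read_specimen_table(fh)


def load_ref_58s() -> str:
    """The packaged synthetic 153-bp 5.8S reference sequence."""
    with (_DATA / "ref_58s_synthetic.fasta").open() as fh:
        lines = [ln.strip() for ln in fh if not ln.startswith(">")]
    return "".join(lines)
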