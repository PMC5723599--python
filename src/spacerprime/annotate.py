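"""Landmark-anchored partitioning of rDNA cassettes into
18S-tail / ITS1 / 5.8S / ITS2 / 28S-head.

The cassette structure exploited here: the pentamer CATTA marks the 3' end
of 18S (ITS1 starts right after it); the 5.8S gene is short (~153 bp in
clitellates) and conserved, so it is located by seeding a fixed reference
at the best occurrence of a conserved 5.8S anchor (by default the 606F
primer site, which sits on the CM1 motif); and the ITS2 end is
operationalized as the start of a conserved 28S anchor (by default the
reverse complement of the 1082R primer).  Profile-HMM scanning is
deliberately out of scope - the landmarks are the conserved elements the
primers themselves were designed on.

Suspect (pseudogene-like) 5.8S copies are flagged by atypical length
(outside 153 +/- 1) or by missing conserved motifs (CM1-CM3 after Harpke &
Peterson; CM1 here is the clitellate variant fully matched by 606F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import io, iupac
from .pcr import find_motif
from .records import SeqRecord

log = logging.getLogger(__name__)

PARTITIONS = ("tail18S", "ITS1", "r58S", "ITS2", "head28S")

#: conserved 5.8S motifs used for pseudogene screening
CM_MOTIFS: dict[str, str] = {
    "CM1": "CGATGAAGAGCGCAGC",
    "CM2": "GAATTGCAGAAYTC",
    "CM3": "TTTGAACGCA",
}

#: symbol emitted for an absent partition
ABSENT = "-"

Interval = tuple[int, int]


@dataclass
class LandmarkSet:
    """The conserved elements used to anchor the annotation."""

    motif_18s_end: str = "CATTA"
    anchor_58s: str = "GTCGATGAAGAGCGCAGCCA"   # 606F site / CM1 region
    anchor_28s: str = "AAGCGGAGGAAAAGAAACTAA"  # reverse complement of 1082R
    max_anchor_mismatches: int = 2

    def __post_init__(self) -> None:
        for name in ("motif_18s_end", "anchor_58s", "anchor_28s"):
            value = iupac.validate(getattr(self, name))
            if not value:
                raise ValueError(f"empty landmark {name}")
            setattr(self, name, value)


@dataclass
class ItsAnnotation:
    """Coordinates (0-based, half-open) and completeness flags for the five
    cassette partitions.  A partition is *complete* when both of its
    boundaries were resolved; a present-but-incomplete partition is
    reported with the '>' length convention."""

    seq_id: str
    partitions: dict[str, Interval | None] = field(
        default_factory=lambda: {k: None for k in PARTITIONS})
    complete: dict[str, bool] = field(
        default_factory=lambda: {k: False for k in PARTITIONS})

    def length(self, key: str) -> int | None:
        iv = self.partitions[key]
        return None if iv is None else iv[1] - iv[0]

    def check_ordering(self) -> bool:
        """Present intervals must be non-overlapping and in cassette order."""
        present = [self.partitions[k] for k in PARTITIONS if self.partitions[k]]
        return all(a[0] <= a[1] <= b[0] for a, b in zip(present, present[1:])) and \
            all(a[0] <= a[1] for a in present)


def find_landmarks(record: SeqRecord, landmarks: LandmarkSet | None = None,
                   ) -> list[tuple[str, Interval, int]]:
    """Locate the landmarks on an unaligned cassette, in cassette order.

    For each anchor the best (fewest-mismatch, then leftmost) occurrence
    within the budget is taken.  The short 18S-end motif is matched exactly
    and, because it is only meaningful as the 18S terminus, the occurrence
    *closest upstream* of the 5.8S anchor is chosen; occurrences conflicting
    with cassette order are dropped.  Absence is a valid result.
    """
    lm = landmarks or LandmarkSet()
    seq = record.sequence
    found: list[tuple[str, Interval, int]] = []

    a58_sites = find_motif(seq, lm.anchor_58s, lm.max_anchor_mismatches)
    a58 = min(a58_sites, key=lambda s: (s[1], s[0])) if a58_sites else None
    a58_iv = (a58[0], a58[0] + len(lm.anchor_58s)) if a58 else None

    catta_sites = find_motif(seq, lm.motif_18s_end, 0)
    if a58_iv is not None:
        catta_sites = [s for s in catta_sites
                       if s[0] + len(lm.motif_18s_end) <= a58_iv[0]]
        catta = catta_sites[-1] if catta_sites else None  # closest upstream
    else:
        catta = catta_sites[0] if catta_sites else None

    a28_sites = find_motif(seq, lm.anchor_28s, lm.max_anchor_mismatches)
    floor = a58_iv[1] if a58_iv else (
        catta[0] + len(lm.motif_18s_end) if catta else 0)
    a28_sites = [s for s in a28_sites if s[0] >= floor]
    a28 = min(a28_sites, key=lambda s: (s[1], s[0])) if a28_sites else None

    if catta:
        found.append(("motif_18s_end",
                      (catta[0], catta[0] + len(lm.motif_18s_end)), catta[1]))
    if a58:
        found.append(("anchor_58s", a58_iv, a58[1]))
    if a28:
        found.append(("anchor_28s", (a28[0], a28[0] + len(lm.anchor_28s)), a28[1]))
    return found


def _place_ref(seq: str, ref: str, anchor_iv: Interval, anchor_offset: int,
               slack: int = 2) -> tuple[int, int]:
    """Seed the 5.8S reference at the anchor and slide +/-slack columns to
    the fewest-mismatch placement (leftmost tie).  Returns the *unclamped*
    (start, end) of the reference window on the template."""
    n, L = len(seq), len(ref)
    ideal = anchor_iv[0] - anchor_offset
    best = None
    for delta in range(-slack, slack + 1):
        start = ideal + delta
        lo, hi = max(0, start), min(n, start + L)
        if hi <= lo:
            continue
        mm, _ = _window_mismatches(ref[lo - start : hi - start], seq[lo:hi])
        score = mm + (L - (hi - lo))  # truncation counts against placement
        if best is None or score < best[0]:
            best = (score, start)
    assert best is not None
    return best[1], best[1] + L


def _window_mismatches(a: str, b: str) -> tuple[int, list[int]]:
    pos = [i for i, (x, y) in enumerate(zip(a, b))
           if not iupac.MASKS[x] & iupac.MASKS[y]]
    return len(pos), pos


def annotate_its(record: SeqRecord, landmarks: LandmarkSet | None = None,
                 ref_58s: str | None = None) -> ItsAnnotation:
    """Partition a cassette using the landmark conventions.

    ITS1 runs from the end of the 18S-terminal CATTA to the start of 5.8S;
    5.8S is the reference window seeded at the conserved anchor; ITS2 runs
    from the end of 5.8S to the start of the 28S anchor.  Partitions whose
    outer boundary is missing are flagged incomplete (the 18S tail and 28S
    head always are, since the cassette carries only partial flanks).
    """
    lm = landmarks or LandmarkSet()
    ref = iupac.validate(ref_58s) if ref_58s else io.load_ref_58s()
    anchor_in_ref = find_motif(ref, lm.anchor_58s, 0)
    if not anchor_in_ref:
        raise ValueError("5.8S reference does not contain the 5.8S anchor")
    anchor_offset = anchor_in_ref[0][0]

    seq, n = record.sequence, len(record.sequence)
    marks = dict((name, iv) for name, iv, _ in find_landmarks(record, lm))
    ann = ItsAnnotation(seq_id=record.id)
    if not marks:
        log.warning("%s: no landmark found; all partitions absent", record.id)
        return ann

    catta = marks.get("motif_18s_end")
    a58 = marks.get("anchor_58s")
    a28 = marks.get("anchor_28s")

    if catta:
        ann.partitions["tail18S"] = (0, catta[1])
        ann.complete["tail18S"] = False  # 18S start is never on the cassette

    s58 = None
    if a58:
        raw_start, raw_end = _place_ref(seq, ref, a58, anchor_offset)
        s58 = (max(0, raw_start), min(n, raw_end))
        ann.partitions["r58S"] = s58
        ann.complete["r58S"] = raw_start >= 0 and raw_end <= n
        if catta and catta[1] > s58[0]:  # conflicting CATTA placement: drop it
            ann.partitions["tail18S"] = None
            catta = None

    if s58:
        if catta:
            ann.partitions["ITS1"] = (catta[1], s58[0])
            ann.complete["ITS1"] = True
        elif s58[0] > 0:
            ann.partitions["ITS1"] = (0, s58[0])
            ann.complete["ITS1"] = False
    elif catta and catta[1] < n:
        ann.partitions["ITS1"] = (catta[1], n)
        ann.complete["ITS1"] = False

    if s58:
        end_known = ann.complete["r58S"]
        if a28:
            ann.partitions["ITS2"] = (s58[1], a28[0])
            ann.complete["ITS2"] = end_known
        elif s58[1] < n:
            ann.partitions["ITS2"] = (s58[1], n)
            ann.complete["ITS2"] = False
    if a28:
        ann.partitions["head28S"] = (a28[0], n)
        ann.complete["head28S"] = False  # 28S end is never on the cassette
    return ann


def validate_58s(ann: ItsAnnotation, record: SeqRecord,
                 motifs: dict[str, str] | None = None,
                 max_mm: int = 2) -> str:
    """Pseudogene screen of a complete 5.8S annotation.

    Returns ``"ok"`` iff the 5.8S length is within 153 +/- 1 *and* every
    configured conserved motif occurs inside it under the mismatch budget;
    otherwise ``"length_atypical"`` or ``"motif_missing"``.
    """
    iv = ann.partitions["r58S"]
    if iv is None or not ann.complete["r58S"]:
        raise ValueError(f"{ann.seq_id}: 5.8S is not completely annotated")
    if not (152 <= iv[1] - iv[0] <= 154):
        return "length_atypical"
    sub = record.sequence[iv[0] : iv[1]]
    for motif in (motifs or CM_MOTIFS).values():
        if not find_motif(sub, motif, max_mm):
            return "motif_missing"
    return "ok"


def partition_lengths(ann: ItsAnnotation) -> tuple[str, str, str, str]:
    """Table-style length strings (seq_id, ITS1, 5.8S, ITS2): complete
    partitions print bare integers, incomplete ones '>' + observed length,
    absent ones '-'."""
    out = [ann.seq_id]
    for key in ("ITS1", "r58S", "ITS2"):
        n = ann.length(key)
        if n is None:
            out.append(ABSENT)
        elif ann.complete[key]:
            out.append(str(n))
        else:
            out.append(f">{n}")
    return tuple(out)
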