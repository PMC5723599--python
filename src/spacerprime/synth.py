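"""Synthetic rDNA cassettes with known ground truth.

A cassette is assembled as

    [18S tail ... 29F site, CATTA] [ITS1] [5.8S] [ITS2] [28S head]

where the 5.8S is a copy of the packaged synthetic 153-bp reference (which
embeds the 606F/CM1 site at offset 10) and the 28S head starts with the
reverse complement of 1082R followed by "CA", so that the longer 1084R
(reverse complement ...CTAACR) also matches exactly.  A chosen number of
mismatches can be planted into the ITS2-pair sites; planted mismatches are
guaranteed real under IUPAC set matching (the replacement base is outside
the primer's set at that position).

Generated spacers are scrubbed so that CATTA occurs nowhere between the
18S-terminal motif and the 5.8S anchor - on real sequences a spurious
spacer CATTA would mislead any motif-based ITS1 delimiter, and the
generator's job is to provide cassettes whose true boundaries the
landmark annotator can be held to exactly.

Everything is reproducible from the spec's seed (one seeded RNG stream per
cassette).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import io, iupac
from .annotate import ItsAnnotation, LandmarkSet
from .records import PrimerPair, SeqRecord

_BASES = np.array(list("ACGT"))


@dataclass
class CassetteSpec:
    """Layout and noise parameters of one synthetic cassette.

    Spacer-length defaults sit inside the ranges observed for clitellates
    (ITS1 314-1117 bp, ITS2 174-503 bp); GC defaults to the ~59% measured
    on successfully amplified spacers.
    """

    tail18S_len: int = 90
    ITS1_len: int = 450
    r58S_len: int = 153
    ITS2_len: int = 300
    head28S_len: int = 80
    gc: float = 0.59
    fwd_site_mm: int = 0
    rev_site_mm: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tail18S_len", "ITS1_len", "r58S_len", "ITS2_len", "head28S_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth returned alongside a generated cassette."""

    boundaries: dict[str, tuple[int, int]]
    fwd_site: tuple[int, int]
    rev_site: tuple[int, int]
    fwd_mm: int
    rev_mm: int
    site_29f: tuple[int, int]
    site_1084r: tuple[int, int]
    gc: float


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def mutate_window(seq: str, interval: tuple[int, int], k: int, seed: int,
                  forbidden: tuple[int, ...] = ()) -> str:
    """Change exactly *k* positions inside *interval* to a different base,
    avoiding *forbidden* (absolute) positions.  Deterministic per seed."""
    start, end = interval
    pool = [i for i in range(start, end) if i not in set(forbidden)]
    if k > len(pool):
        raise ValueError(f"cannot plant {k} mutations in {len(pool)} positions")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    chars = list(seq)
    for idx in sorted(int(c) for c in chosen):
        pos = pool[idx]
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def _plant_primer_mismatches(chars: list[str], site_start: int, primer_seq: str,
                             k: int, rng: np.random.Generator) -> None:
    """Plant exactly *k* real mismatches against an IUPAC primer laid at
    *site_start*: replacement bases are outside the primer's set at the
    chosen positions (in place)."""
    eligible = [i for i, ch in enumerate(primer_seq) if len(iupac.SETS[ch]) < 4]
    if k > len(eligible):
        raise ValueError(f"cannot plant {k} mismatches against {primer_seq}")
    chosen = rng.choice(len(eligible), size=k, replace=False)
    for idx in sorted(int(c) for c in chosen):
        p = eligible[idx]
        options = [b for b in "ACGT" if b not in iupac.SETS[primer_seq[p]]]
        chars[site_start + p] = options[int(rng.integers(len(options)))]


def _build_58s(ref: str, target_len: int, rng: np.random.Generator,
               gc: float) -> str:
    """The reference 5.8S, optionally stretched/shrunk (inside the
    motif-free zone at columns 35-55) to an atypical length."""
    if target_len == len(ref):
        return ref
    delta = target_len - len(ref)
    if delta < 0:
        if -delta > 15:
            raise ValueError("5.8S shrink exceeds the motif-free zone")
        return ref[:40] + ref[40 - delta:]   # delete |delta| bases at col 40
    return ref[:45] + _random_seq(rng, delta, gc) + ref[45:]


def _scrub_motif(chars: list[str], motif: str, lo: int, hi: int,
                 patch_lo: int, patch_hi: int, rng: np.random.Generator) -> None:
    """Remove every *motif* occurrence whose start lies in [lo, hi) by
    patching one of its bases inside the region [patch_lo, patch_hi)
    (in place)."""
    for _ in range(200):
        text = "".join(chars)
        pos = text.find(motif, lo)
        if pos == -1 or pos >= hi:
            return
        idxs = [i for i in range(pos, pos + len(motif)) if patch_lo <= i < patch_hi]
        if not idxs:  # occurrence not patchable (overlaps a planted site)
            lo = pos + 1
            continue
        i = idxs[int(rng.integers(len(idxs)))]
        motif_char = motif[i - pos]
        options = [b for b in "ACGT" if b != motif_char and b != chars[i]]
        chars[i] = options[int(rng.integers(len(options)))]
    raise RuntimeError("motif scrub did not converge")


def make_cassette(spec: CassetteSpec, primers: PrimerPair | None = None,
                  landmarks: LandmarkSet | None = None,
                  ) -> tuple[SeqRecord, ItsAnnotation, PlantedTruth]:
    """Generate one cassette, its true annotation, and the planted truth.

    *primers* is the ITS2-style pair whose sites receive the planted
    mismatches (default 606F/1082R); *landmarks* only supplies the 18S-end
    motif (default CATTA).
    """
    pair = primers or io.its2_pair()
    lm = landmarks or LandmarkSet()
    all_primers = io.load_its_primers()
    seq_29f = all_primers["29F"].seq
    rc_1084r = iupac.reverse_complement(all_primers["1084R"].seq)

    ref = io.load_ref_58s()
    motif = lm.motif_18s_end
    flank_min = len(seq_29f) + len(motif)
    if spec.tail18S_len < flank_min:
        raise ValueError(f"tail18S_len must be >= {flank_min}")
    rc_rev = iupac.reverse_complement(pair.rev.seq)
    # the 28S head must hold the 1082R complement plus the CA that completes
    # the 1084R complement
    head_site_len = len(rc_rev) + 2
    if spec.head28S_len < head_site_len:
        raise ValueError(f"head28S_len must be >= {head_site_len}")
    if spec.fwd_site_mm > len(pair.fwd.seq) or spec.rev_site_mm > len(pair.rev.seq):
        raise ValueError("planted mismatch count exceeds primer length")

    rng = np.random.default_rng(spec.seed)
    tail = (_random_seq(rng, spec.tail18S_len - flank_min, spec.gc)
            + seq_29f + motif)
    its1 = _random_seq(rng, spec.ITS1_len, spec.gc)
    r58 = _build_58s(ref, spec.r58S_len, rng, spec.gc)
    its2 = _random_seq(rng, spec.ITS2_len, spec.gc)
    head = rc_rev + "CA" + _random_seq(rng, spec.head28S_len - head_site_len, spec.gc)

    t0 = spec.tail18S_len
    b = {
        "tail18S": (0, t0),
        "ITS1": (t0, t0 + spec.ITS1_len),
        "r58S": (t0 + spec.ITS1_len, t0 + spec.ITS1_len + len(r58)),
        "ITS2": (t0 + spec.ITS1_len + len(r58),
                 t0 + spec.ITS1_len + len(r58) + spec.ITS2_len),
        "head28S": (t0 + spec.ITS1_len + len(r58) + spec.ITS2_len,
                    t0 + spec.ITS1_len + len(r58) + spec.ITS2_len + spec.head28S_len),
    }
    anchor_off = 10  # offset of the 606F/CM1 site within the reference
    fwd_site = (b["r58S"][0] + anchor_off, b["r58S"][0] + anchor_off + len(pair.fwd.seq))
    rev_site = (b["head28S"][0], b["head28S"][0] + len(rc_rev))
    site_29f = (t0 - flank_min, t0 - len(motif))
    site_1084r = (rev_site[0], rev_site[0] + len(rc_1084r))

    chars = list(tail + its1 + r58 + its2 + head)
    _plant_primer_mismatches(chars, fwd_site[0], pair.fwd.seq,
                             spec.fwd_site_mm, rng)
    # the reverse site holds the primer's reverse complement, so plant
    # against the complement text (positions are site-relative)
    _plant_primer_mismatches(chars, rev_site[0], rc_rev, spec.rev_site_mm, rng)
    # no 18S-end motif may start after the terminal one and before the 5.8S
    # anchor; patch only inside ITS1 (the flanks carry planted sites)
    _scrub_motif(chars, motif, t0 - len(motif) + 1, fwd_site[0],
                 b["ITS1"][0], b["ITS1"][1], rng)

    record = SeqRecord(id=f"synth_{spec.seed}", sequence="".join(chars),
                       is_target=True)
    ann = ItsAnnotation(seq_id=record.id, partitions=dict(b),
                        complete={"tail18S": False, "ITS1": True, "r58S": True,
                                  "ITS2": True, "head28S": False})
    truth = PlantedTruth(boundaries=dict(b), fwd_site=fwd_site, rev_site=rev_site,
                         fwd_mm=spec.fwd_site_mm, rev_mm=spec.rev_site_mm,
                         site_29f=site_29f, site_1084r=site_1084r, gc=spec.gc)
    return record, ann, truth


DEFAULT_RANGES: dict[str, tuple[int, int]] = {
    "tail18S_len": (60, 120),
    "ITS1_len": (314, 1117),
    "ITS2_len": (174, 503),
    "head28S_len": (60, 120),
}


def make_panel(n_target: int, n_offtarget: int,
               spec_ranges: dict[str, tuple[int, int]] | None = None,
               seed: int = 0, primers: PrimerPair | None = None,
               gc: float = 0.59,
               ) -> list[tuple[SeqRecord, PlantedTruth]]:
    """A labelled database of target and off-target cassettes.

    Target cassettes carry 0-1 planted mismatches per ITS2-pair site;
    off-target cassettes carry >= 4 mismatches in both forward sites (the
    5.8S one and the 29F one), so they never amplify within a 3-mismatch
    budget.  Spacer lengths are drawn uniformly within *spec_ranges*.
    """
    pair = primers or io.its2_pair()
    ranges = {**DEFAULT_RANGES, **(spec_ranges or {})}
    rng = np.random.default_rng(seed)
    all_primers = io.load_its_primers()
    seq_29f = all_primers["29F"].seq

    panel: list[tuple[SeqRecord, PlantedTruth]] = []
    for i in range(n_target + n_offtarget):
        target = i < n_target
        lengths = {k: int(rng.integers(lo, hi + 1)) for k, (lo, hi) in ranges.items()}
        if target:
            fwd_mm, rev_mm = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        else:
            fwd_mm, rev_mm = int(rng.integers(4, 9)), 0
        spec = CassetteSpec(gc=gc, fwd_site_mm=fwd_mm, rev_site_mm=rev_mm,
                            seed=int(rng.integers(2**31 - 1)), **lengths)
        rec, _, truth = make_cassette(spec, primers=pair)
        rec = replace(
            rec,
            id=f"{'target' if target else 'offtarget'}_{i}",
            family="Targetidae" if target else "Otheridae",
            species=f"{'Targetus' if target else 'Otherus'} sp{i}",
            is_target=target,
        )
        if not target:
            # knock out the whole-ITS forward site as well
            chars = list(rec.sequence)
            sub_rng = np.random.default_rng(spec.seed + 1)
            _plant_primer_mismatches(chars, truth.site_29f[0], seq_29f,
                                     int(sub_rng.integers(4, 9)), sub_rng)
            rec = replace(rec, sequence="".join(chars))
        panel.append((rec, truth))
    return panel
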