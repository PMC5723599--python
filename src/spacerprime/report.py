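"""Aggregation of in silico PCR and annotation results.

Three reporting surfaces: e-class specificity tables (how many target vs
off-target sequences amplify with 0, 1, 2, 3 mismatches), per-position
primer mismatch profiles over unique annealing-region haplotypes, and
amplicon summary statistics.  Counting is per *sequence*, not per amplicon:
each template contributes its best (lowest e-class) hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import iupac
from .annotate import ItsAnnotation
from .pcr import AmpliconHit, best_per_template, count_mismatches, find_motif
from .records import Primer, SeqRecord

log = logging.getLogger(__name__)

E_CLASSES = ("e0", "e1", "e2", "e3")
GROUPS = ("target", "off_target")


@dataclass
class SpecificityTable:
    """Per-pair, per-e-class amplified-sequence counts split by target vs
    off-target taxa."""

    pair_name: str
    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: {e: 0 for e in E_CLASSES} for g in GROUPS})

    def total(self, group: str) -> int:
        return sum(self.counts[group].values())

    def cumulative(self, group: str, e_class: str) -> int:
        """Sequences amplified at *or below* the given e-class (the
        'e<=k' reading of cumulative bars)."""
        upto = E_CLASSES.index(e_class)
        return sum(self.counts[group][E_CLASSES[i]] for i in range(upto + 1))

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready frame with fixed column order; both per-class (e=k)
        and cumulative (e<=k) columns are emitted."""
        rows = []
        for group in GROUPS:
            row = {"pair": self.pair_name, "group": group}
            row.update({e: self.counts[group][e] for e in E_CLASSES})
            row.update({f"le_{e}": self.cumulative(group, e) for e in E_CLASSES})
            rows.append(row)
        return pd.DataFrame(rows)


def build_specificity_table(hits: Iterable[AmpliconHit], db: Sequence[SeqRecord],
                            pair_name: str | None = None) -> SpecificityTable:
    """Count each amplified sequence once, in the e-class of its best hit,
    in its target/off-target group.  *hits* may be raw amplify output; they
    are collapsed per template first (idempotent on already-collapsed
    input)."""
    is_target = {rec.id: rec.is_target for rec in db}
    collapsed = best_per_template(hits)
    if pair_name is not None:
        collapsed = [h for h in collapsed if h.pair_name == pair_name]
        name = pair_name
    else:
        names = {h.pair_name for h in collapsed}
        if len(names) > 1:
            raise ValueError(f"hits span several pairs {sorted(names)}; "
                             "pass pair_name")
        name = names.pop() if names else ""
    table = SpecificityTable(pair_name=name)
    for h in collapsed:
        if h.template_id not in is_target:
            raise KeyError(f"hit references unknown template {h.template_id!r}")
        group = "target" if is_target[h.template_id] else "off_target"
        if h.e_index < len(E_CLASSES):
            table.counts[group][h.e_class] += 1
    return table


@dataclass
class MismatchProfile:
    """Per-haplotype mismatch indicator vectors over primer positions,
    ranked by total mismatches (ties broken by haplotype string)."""

    primer_name: str
    haplotypes: list[str]          # unique annealing-region windows
    rows: list[tuple[int, ...]]    # 0/1 indicators, len == primer length
    seq_ids: list[tuple[str, ...]] # record ids collapsed into each haplotype

    def totals(self) -> list[int]:
        return [sum(r) for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows,
                          columns=[f"p{i + 1}" for i in range(len(self.rows[0]))]
                          if self.rows else [])
        df.insert(0, "haplotype", self.haplotypes)
        df.insert(1, "n_seqs", [len(ids) for ids in self.seq_ids])
        df["total"] = self.totals()
        return df


def mismatch_profile(primer: Primer,
                     annotated: Sequence[tuple[SeqRecord, ItsAnnotation]],
                     partition: str = "r58S") -> MismatchProfile:
    """Collapse the primer's annealing windows (its best site inside the
    given partition of each record) into unique haplotypes and rank them by
    mismatch total.  Records lacking the partition are skipped with a
    warning."""
    L = len(primer.seq)
    groups: dict[str, list[str]] = {}
    for rec, ann in annotated:
        iv = ann.partitions.get(partition)
        if iv is None or iv[1] - iv[0] < L:
            log.warning("%s: partition %s unavailable; skipped", rec.id, partition)
            continue
        sub = rec.sequence[iv[0] : iv[1]]
        sites = find_motif(sub, primer.seq, max_mm=L)  # best site whatever the distance
        start = min(sites, key=lambda s: (s[1], s[0]))[0]
        window = sub[start : start + L]
        groups.setdefault(window, []).append(rec.id)

    entries = []
    for window, ids in groups.items():
        _, pos = count_mismatches(primer, window)
        indicators = tuple(1 if i in set(pos) else 0 for i in range(L))
        entries.append((sum(indicators), window, indicators, tuple(sorted(ids))))
    entries.sort(key=lambda e: (e[0], e[1]))
    return MismatchProfile(
        primer_name=primer.name,
        haplotypes=[e[1] for e in entries],
        rows=[e[2] for e in entries],
        seq_ids=[e[3] for e in entries],
    )


def amplicon_stats(hits: Iterable[AmpliconHit], db: Sequence[SeqRecord]) -> dict:
    """Length min/max/mean (primer-inclusive) and mean insert GC fraction.

    GC is computed on unambiguous bases only.  An empty hit list yields an
    empty summary (n == 0, other fields None).
    """
    by_id = {rec.id: rec for rec in db}
    lengths, gcs = [], []
    for h in hits:
        lengths.append(h.length)
        insert = by_id[h.template_id].sequence[h.insert_start : h.insert_end]
        if insert:
            gcs.append(iupac.gc_fraction(insert))
    if not lengths:
        return {"n": 0, "length_min": None, "length_max": None,
                "length_mean": None, "gc_mean": None}
    return {
        "n": len(lengths),
        "length_min": min(lengths),
        "length_max": max(lengths),
        "length_mean": sum(lengths) / len(lengths),
        "gc_mean": sum(gcs) / len(gcs) if gcs else None,
    }


def success_filter(hits: Iterable[AmpliconHit], min_len: int = 200) -> list[AmpliconHit]:
    """Keep hits whose primer-inclusive length reaches the success
    threshold (amplicons >= 200 bp counted as successful).  Idempotent."""
    return [h for h in hits if h.length >= min_len]
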