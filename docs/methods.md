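# Methods

## The cassette model

The unit of analysis is an rDNA cassette: a partial 18S tail, the fast
evolving ITS1 spacer, the short conserved 5.8S gene, the ITS2 spacer, and
a partial 28S head.  In clitellate annelids the published spacer lengths
span 314–1117 bp (ITS1) and 174–503 bp (ITS2), nearly all complete 5.8S
copies are 153 bp (one known 154 bp exception), and spacer GC is around
59%.  These numbers parameterize both the annotator's sanity checks and
the synthetic generator's defaults.

## Landmark-anchored annotation

Profile-HMM annotators (ITSx-style) delimit ITS partitions with
full-length rRNA models.  This package instead anchors on three short
conserved elements — the same elements clade-specific primers are designed
on:

1. **18S terminus**: the pentamer `CATTA`, matched exactly (a 5-mer under
   a mismatch budget would match everywhere).  When several occurrences
   precede the 5.8S anchor the one *closest upstream* of it is taken,
   since the motif is only meaningful as the 18S terminus.
2. **5.8S anchor**: the 606F site (20-mer on the conserved motif CM1),
   matched under a budget of 2 mismatches (the observed spread across
   clitellate haplotypes); best = fewest mismatches, then leftmost.
3. **28S anchor**: the reverse complement of 1082R (21-mer), same budget,
   constrained to lie downstream of the 5.8S anchor.

The 5.8S interval is obtained by seeding the packaged 153-bp reference at
the anchor (the anchor sits at a fixed reference offset) and sliding ± 2
columns to the fewest-mismatch placement, leftmost on ties.  ITS1 is
`(end of CATTA, start of 5.8S)`, ITS2 is `(end of 5.8S, start of the 28S
anchor)`.  A partition whose outer boundary falls off the sequence is kept
but flagged incomplete and reported with the `>` length convention; the
18S tail and 28S head are always incomplete because the cassette carries
only partial flanks.

**The 5.8S reference is synthetic.**  Building a consensus from the
deposited accessions would require downloads, so the package ships a
153-bp sequence generated once (seed 20170929) with the 606F/CM1 site at
offset 10, the conserved motifs CM2 (`GAATTGCAGAAYTC`) and CM3
(`TTTGAACGCA`) at offsets 60 and 100, GC 0.556, and no internal `CATTA`.
Against real clitellate 5.8S the *placement* logic is unchanged (it is
anchor-seeded), but the per-column mismatch score of the slide step is
meaningful only near the anchor; and because the reference has a fixed
length, a genuine 154-bp 5.8S is reported as 153 bp.  The pseudogene
screen (`validate_58s`) answers `ok` iff length ∈ 153 ± 1 and all three
CM motifs occur within 2 mismatches; otherwise `length_atypical` or
`motif_missing`.

## Mismatch-tolerant matching

Every IUPAC symbol is a 4-bit mask over {A,C,G,T}; two symbols match iff
their masks intersect, so `Y` vs `C` matches and a template `N` matches
any primer base — a symmetric, documented rule.  The scanner slides the
primer mask vector along the template mask vector (a numpy loop over the
≤ 25 primer positions, linear in template length — adequate at desk
scale) and reports every window within the budget, on both strands.
Mismatches are position-blind: no 3'-end weighting in matching; the known
poor extension of 3'-terminal-A primers with Taq polymerase is instead a
design-time scoring flag.

`amplify` emits every forward-site × downstream-reverse-site combination
whose primer-inclusive length lies in the pair's window, in both pair
orientations (so amplifying the reverse complement of a template yields
the mirror-image hit set, with each mismatch count still attached to its
primer).  Nested and overlapping amplicons are all reported; per-sequence
counting (specificity tables) collapses to each template's best hit —
lowest e-class, then leftmost, then shortest.  The e-class of a hit is
`e{max(fwd_mm, rev_mm)}`; with the conventional budget of 3 mismatches
per primer the classes e0–e3 partition the hits.

Amplicon length filters are primer-inclusive (the simulated whole-ITS
window 400–2500 bp and ITS2 window 200–1250 bp describe whole fragments);
insert coordinates are reported alongside for trimming workflows.  The
mismatch budget is per primer, not per pair, following the reading that
the tolerance applies "between a primer and its annealing sequence".
Amplicons of at least 200 bp count as successful (`success_filter`).

## Conserved-window design

Column identity is the frequency of the modal non-gap base among non-gap
rows (an all-gap column scores 0).  Conserved windows are maximal runs of
at least 15 consecutive columns — the smallest integer satisfying
">14 nucleotides" — with identity ≥ 0.90 and gap fraction ≤ 0.10;
the thresholds are chosen so that a conserved 5.8S region qualifies while
typical spacer columns do not.  The IUPAC consensus includes every base
whose non-gap column frequency reaches the minor-base floor (default
0.10); majority consensus takes the modal base with an alphabetic
tiebreak.  Gap-majority columns are dropped from consensus strings, and
windows whose consensus shrank that way are skipped for candidate
enumeration (their column coordinates would drift).

Candidates are consensus k-mers (default 20 nt, degeneracy capped at 8 —
the published primers have degeneracy ≤ 2), named positionally
(`<column+1>F` / `<column>R`) as is customary for rDNA primers.  The
composite score starts at 100 and subtracts documented penalties:
|Tm − 60| °C, GC outside 0.40–0.60 (50 per unit), degeneracy above the
cap (5 per doubling step), hairpin stems > 4 bp and self-dimer runs
> 6 bp (3 per extra base), and 10 for a 3'-terminal A.  The weights are
config-exposed (`ScoreParams`); the score is a stand-in for proprietary
design-suite scores, not a reproduction of any.

Tm: Wallace `2(A+T) + 4(G+C)`, or nearest-neighbor (SantaLucia unified
parameters via Biopython) under PCR-typical conditions — 250 nM primer,
50 mM monovalent salt, 1.5 mM Mg²⁺ with the Owczarzy correction; under
these conditions the two estimates agree within 8 °C for 18–25-mers.
Degenerate primers take the lowest-Tm expansion (the worst variant in the
mixture).  Pairing requires the median (across rows) ungapped product
length to lie in the bounds and |ΔTm| ≤ 8 °C by the Wallace rule; the
8 °C default reflects that rule's coarseness — the published ITS2 pair
itself differs by 6 °C under it while being Tm-matched by design.
Ranking: combined composite, then shorter product, then name.

## The synthetic generator

`make_cassette` assembles `random 18S tail + 29F site + CATTA`, a random
ITS1, a copy of the 5.8S reference, a random ITS2, and a 28S head that
starts with the 1082R complement followed by `CA` (which completes the
1084R complement, so both published pairs amplify every unmutated
cassette).  Planted primer-site mismatches are *guaranteed real*: the
replacement base is drawn from outside the primer's IUPAC set at that
position.  Spacers are generated at the requested GC (default 0.59) and
scrubbed so no `CATTA` starts between the 18S terminus and the 5.8S
anchor — otherwise a spurious spacer occurrence (expected about once per
kb of random sequence) would defeat any motif-based ITS1 delimiter, and
the generator's purpose is to hold the annotator to exact boundaries.
Atypical 5.8S lengths (for exercising the pseudogene screen) are produced
by inserting or deleting bases in a motif-free zone of the reference.

`make_panel` draws spacer lengths uniformly from the observed ranges,
plants 0–1 mismatches per site on target cassettes and ≥ 4 mismatches in
both forward sites on off-target cassettes, and labels records
accordingly.  Every cassette derives from one seeded RNG stream, so
panels are bit-reproducible across platforms.

What the generator does **not** emulate: phylogenetic covariance
(mutations are independent, not tree-shaped), indels in spacers, intra-
individual polymorphism and polyploid copy variation, chimeras, and real
5.8S haplotype structure.  Tests passing on synthetic panels therefore
demonstrate the correctness of the bookkeeping (coordinates, mismatch
counting, e-class partitioning, boundary recovery) under the stated
conditions — not annotator performance on divergent real amplicons, which
is bounded by the landmark assumptions above.

## Numerical and determinism choices

Coordinates are 0-based half-open throughout (`length = end − start`).
Ties break deterministically everywhere: fewest mismatches then leftmost
for landmark and 5.8S placement, leftmost for equal-score reference
slides, e-class/start/length for best-per-template collapsing,
composite/product/name for pair ranking, mismatch-total then haplotype
string for profile rows.  Haplotype collapsing uses exact string identity
of the annealing window.  GC content excludes ambiguity codes from both
numerator and denominator.  `U` is silently read as `T`; status and
absence glyphs are emitted as ASCII (`+`, `-`, `+/-`, `>`).  Amplicon
FASTA ids are `<template>:<start>-<end>:<pair>` so multi-hit templates
stay unique, and re-writing the same hits is byte-identical.

Problem sizes used by the shipped checks — 1,000-cassette e-class panels,
1,000-template oracle comparisons, 500-cassette annotation round trips,
30-row design alignments — keep every property exact (planted
distributions are recovered with equality, not within tolerance) while a
full run stays in the seconds range.

## Known limitations

- The annotator requires the 5.8S anchor region to be present; amplicons
  that start downstream of it (e.g. deposits retaining only the 3' end of
  5.8S) get no 5.8S placement and only `>`-style partial lengths.
- Fixed-length 5.8S reference: true 152/154-bp variants are placed at
  153 bp (the screen still judges whatever interval it is given).
- The designer assumes a trustworthy alignment; it does not build one.
- No thermodynamic secondary-structure folding, multiplex compatibility,
  or polymerase-specific extension modeling; complementary-run heuristics
  only.
- EMBL/GenBank-scale specificity counts depend on the database version
  and are out of scope; specificity is evaluated on labelled panels.
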