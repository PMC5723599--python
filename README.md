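# spacerprime

Clade-specific primer design and mismatch-tolerant in silico PCR for the
nuclear rDNA **Internal Transcribed Spacer (ITS) region** — the
ITS1–5.8S–ITS2 stretch between 18S and 28S.  The package is built around
the workflow used to develop clitellate-specific ITS primers (the
whole-ITS pair **29F/1084R** and the ITS2 pair **606F/1082R**, which are
shipped as packaged fixtures together with the 71-specimen verification
panel), but every step is generic: it applies to any rDNA cassette whose
flanks and 5.8S are conserved while the spacers evolve fast.

It is intended for molecular systematists who need to (i) annotate ITS
amplicons into their partitions, (ii) screen candidate primers for clade
specificity before ordering oligos, and (iii) generate ground-truth test
data for either task.

## What it computes

**Annotation.**  A cassette `(18S)-ITS1-5.8S-ITS2-(28S)` is partitioned
with landmark conventions: the conserved pentamer `CATTA` marks the 3' end
of 18S (ITS1 starts right after it); the ~153 bp 5.8S is located by
seeding a packaged reference at the best occurrence of a conserved 5.8S
anchor (the 606F site, which sits on the conserved motif CM1); the ITS2
end is the start of a conserved 28S anchor (the reverse complement of
1082R).  Coordinates are 0-based half-open.  A pseudogene screen flags a
5.8S whose length falls outside 153 ± 1 or which lacks the conserved
motifs CM1–CM3.  Length tables use the field's conventions: `351` for a
complete partition, `>439` for one cut by the sequence end, `-` for
absent.

**In silico PCR.**  Primer *p* anneals at template window *w* iff the
number of positions where the IUPAC sets of *p* and *w* do not intersect
is ≤ the mismatch budget *e* (degenerate bases on either side match by set
intersection; position on the primer is irrelevant).  A pair amplifies
wherever a forward site and a downstream reverse-complement site of the
reverse primer enclose a primer-inclusive product within the length
window, e.g. 400–2500 bp for whole ITS and 200–1250 bp for ITS2.  Each
amplicon is classed **e0–e3** by max(fwd mismatches, rev mismatches), and
specificity tables count each *sequence* once (its best hit), split into
target vs off-target taxa.

**Design.**  On an alignment, maximal runs of ≥ 15 columns with ≥ 90%
identity and ≤ 10% gaps are conserved windows; window-consensus k-mers
become candidates, scored for Tm (Wallace `2(A+T)+4(G+C)` or
nearest-neighbor), GC, degeneracy, hairpin/self-dimer runs and a
3'-terminal-A flag, then paired under product-length and ΔTm constraints.

## Worked example

```
$ python examples/03_insilico_pcr_screen.py
pair 606F/1082R:
  target      e0=2  e1=8  e2=0  e3=0  (total 10)
  off_target  e0=0  e1=0  e2=0  e3=0  (total 0)
amplicons: n=10, length 360-643 bp, mean insert GC 0.575
```

Ten synthetic target cassettes carry 0–1 planted mismatches per primer
site, so all ten amplify at e0/e1; the ten off-target cassettes carry ≥ 4
mismatches in the forward site and never amplify within the 3-mismatch
budget — the e-class split is exactly the planted one.  Amplicon lengths
are the primer-inclusive products (5.8S tail + ITS2 + 28S anchor), and the
insert GC reflects the generator's ~59% spacer GC.

The other examples annotate cassettes (`01_annotate_cassettes.py`) and
rediscover 606F/1082R from conserved windows (`02_design_primers.py`).
A thin CLI wraps the same calls:

```
spacerprime synth --n-target 20 --n-offtarget 20 --seed 42 --out panel.fa --truth truth.tsv
spacerprime annotate --fasta panel.fa --out annotations.tsv
spacerprime ecopcr --db panel.fa -e 3 -l 200 -L 1250 --out hits.tsv
spacerprime report --hits hits.tsv --db panel.fa --out report/
spacerprime design --alignment aln.fa --min-len 200 --max-len 1250 --out candidates.tsv
```

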