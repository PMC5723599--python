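"""Annotate rDNA cassettes into ITS1 / 5.8S / ITS2 partitions.

Generates three synthetic cassettes (one truncated inside ITS1), runs the
landmark annotator, and prints Table-style length rows: bare integers are
complete partitions, '>' marks a partition whose outer boundary is missing,
'-' an absent one.  The last column is the 5.8S pseudogene screen.
"""

import spacerprime as sp

records = []
for seed in (1, 2):
    rec, _, _ = sp.make_cassette(sp.CassetteSpec(seed=seed, ITS1_len=350 + 80 * seed))
    records.append(rec)

# a partial amplicon: sequence starts 100 bp into ITS1, so no CATTA upstream
full, _, truth = sp.make_cassette(sp.CassetteSpec(seed=3))
records.append(sp.SeqRecord("partial", full.sequence[truth.boundaries["ITS1"][0] + 100:]))

print(f"{'seq_id':<10} {'ITS1':>6} {'5.8S':>6} {'ITS2':>6}  5.8S screen")
for rec in records:
    ann = sp.annotate_its(rec)
    seq_id, its1, r58s, its2 = sp.partition_lengths(ann)
    screen = sp.validate_58s(ann, rec) if ann.complete["r58S"] else "-"
    print(f"{seq_id:<10} {its1:>6} {r58s:>6} {its2:>6}  {screen}")
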