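"""Screen a primer pair for clade specificity by in silico PCR.

Generates a labelled panel (10 target cassettes with 0-1 planted primer
mismatches, 10 off-target cassettes with >= 4 mismatches in the forward
site), amplifies with the ITS2 pair 606F/1082R allowing up to 3 mismatches
per primer, and prints the e-class specificity table (e0 = perfect match,
e1-e3 = worst per-primer mismatch count) plus amplicon statistics.
"""

import spacerprime as sp

panel = sp.make_panel(n_target=10, n_offtarget=10, seed=42)
db = [rec for rec, _ in panel]
pair = sp.its2_pair()

hits = sp.run_database(pair, db, max_mm=3)
table = sp.build_specificity_table(hits, db)
print(f"pair {table.pair_name}:")
for group in ("target", "off_target"):
    row = "  ".join(f"{e}={table.counts[group][e]}" for e in ("e0", "e1", "e2", "e3"))
    print(f"  {group:<11} {row}  (total {table.total(group)})")

best = sp.best_per_template(sp.success_filter(hits))
stats = sp.amplicon_stats(best, db)
print(f"amplicons: n={stats['n']}, length {stats['length_min']}-"
      f"{stats['length_max']} bp, mean insert GC {stats['gc_mean']:.3f}")
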