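"""Per-window mismatch profiles and mismatch-site tabulation.

Shows the two window modes on a fragment/comparator pair: the aligned
profile (underlined-stretch style report, mismatch-site counts) and the
k-mer scan that governs off-target risk.
"""

import numpy as np

from vigsdesign import (
    min_distance_scan,
    mismatch_site_table,
    profile_to_tsv,
    render_alignment_report,
    window_mismatches_aligned,
)

rng = np.random.default_rng(5)
bases = np.array(list("ACGT"))
fragment = "".join(bases[rng.integers(0, 4, 90)])

# comparator: same region with substitutions at a few sites
comparator = list(fragment)
for pos in (10, 44, 46, 80):
    comparator[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[comparator[pos]]
comparator = "".join(comparator)

aligned = window_mismatches_aligned(fragment, comparator)
print("aligned-mode counts (first 10 windows):", aligned.counts[:10])

# sites with exactly 1 or 2 mismatches per 21-bp stretch — the stretches
# that can still silence the comparator
table = mismatch_site_table(fragment, {"comparator": comparator})
print("\nmismatch-site table (k = mismatches per 21-bp stretch):")
print(table)

scan = min_distance_scan(fragment, comparator)
print("\nscan-mode minimum distances (first 10):", scan.counts[:10])
print("per-window TSV head:")
print(profile_to_tsv(scan).head(3).to_string(index=False))

print()
print(render_alignment_report(fragment, comparator, highlight_max=2))
# Stretches annotated with <= 2 mismatches per window are the regions a
# designer must drop: one or two mismatches per 21 bp do not prevent
# silencing of the comparator.
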