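"""Score siRNA/target pairings under the miRNA target-recognition rules.

An siRNA that mismatches a transcript can still down-regulate it if the
pairing satisfies the miRNA rules: at most one mismatch at guide
positions 2-12 (the cleavage site 10-11 must pair), a 3' mismatch loop of
at most 2 nt, and a perfect 3' part compensates up to two 5' mismatches.
"""

import numpy as np

from vigsdesign import evaluate_duplex, find_mirna_like_sites, revcomp

rng = np.random.default_rng(3)
bases = np.array(list("ACGT"))
guide = "".join(bases[rng.integers(0, 4, 21)])
SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def site_with(mm_positions=(), loop=""):
    rcs = list(guide)
    for p in mm_positions:
        rcs[p - 1] = SUB[rcs[p - 1]]
    rcs = rcs[:16] + list(loop) + rcs[16:]
    return revcomp("".join(rcs))


for label, site in [
    ("perfect pairing", site_with()),
    ("1 mismatch at position 6", site_with([6])),
    ("2 seed mismatches, 3' perfect", site_with([3, 8])),
    ("2 seed + 1 3' mismatch", site_with([3, 8, 15])),
    ("2-nt 3' loop", site_with(loop="GT")),
    ("3-nt 3' loop", site_with(loop="GTA")),
    ("mismatch at cleavage position 10", site_with([10])),
]:
    ev = evaluate_duplex(guide, site)
    print(f"{label:35s} functional={ev.functional!s:5s} ({ev.reason})")

# scan a transcript for functional sites of this guide
transcript = (
    "".join(bases[rng.integers(0, 4, 60)])
    + site_with(loop="GT")
    + "".join(bases[rng.integers(0, 4, 60)])
)
hits = find_mirna_like_sites(guide, transcript)
print(f"\n{len(hits)} functional site(s) on a 143-nt transcript:")
for h in hits:
    print(
        f"  {h.target_start + 1}-{h.target_end} loop={h.loop_len_3p} "
        f"m5'={h.mismatches_5p} m3'={h.mismatches_3p}"
    )
# Any such hit disqualifies the corresponding fragment window even when
# the plain >= 3-mismatches-per-21-bp rule is met.
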