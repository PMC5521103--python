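"""Independent brute-force oracles used to verify the engines.

These deliberately avoid the implementation's code paths: the scan oracle
compares every fragment k-mer against every transcript k-mer directly (per
window, no diagonal accumulation), and the duplex oracle transcribes the
pairing rules with plain Python loops over every admissible alignment.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_counts_pure(frag: str, tran: str, w: int = 21, both: bool = True) -> list[int]:
    """All-pairs minimum Hamming distance, pure Python."""
    targets = [tran] + ([rc(tran)] if both else [])
    out = []
    for i in range(len(frag) - w + 1):
        km = frag[i : i + w]
        best = w
        for t in targets:
            for j in range(len(t) - w + 1):
                d = hamming(km, t[j : j + w])
                if d < best:
                    best = d
        out.append(best)
    return out


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def scan_counts_brute(frag: str, tran: str, w: int = 21, both: bool = True) -> np.ndarray:
    """All-pairs minimum Hamming distance; brute force per fragment window
    (each window compared against every transcript window directly)."""
    targets = [tran] + ([rc(tran)] if both else [])
    n = len(frag) - w + 1
    out = np.full(n, w, dtype=np.int64)
    for t in targets:
        T = _enc(t)
        if T.size < w:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(T, w)
        for i in range(n):
            d = (wins != _enc(frag[i : i + w])).sum(axis=1).min()
            out[i] = min(out[i], int(d))
    return out


# -- miRNA target-recognition rules, direct transcription -------------------

MAX_5P = 1
MAX_5P_COMP = 2
MAX_3P = 2
MAX_TOTAL = 2
MAX_LOOP = 2


def duplex_functional(guide: str, site: str, max_loop: int = MAX_LOOP) -> bool:
    """True iff some admissible alignment of guide vs site is functional.

    Enumerates every 3'-loop split; for each, counts mismatches in the 5'
    region (guide positions 2-12), the 3' region (13..end), checks the
    cleavage positions 10-11, and applies the rules: at most one 5'
    mismatch (two if the 3' part is perfectly paired and loop-free), at
    most two 3' mismatches, at most two substitution mismatches in total,
    loop of at most two target nucleotides, cleavage site paired,
    position 1 ignored.
    """
    w = len(guide)
    loop = len(site) - w
    if loop < 0:
        raise ValueError("site shorter than guide")
    rcs = rc(site)
    splits = [None] if loop == 0 else list(range(12, w))
    for j in splits:
        if j is None:
            cols = list(range(w))
        else:
            cols = list(range(j)) + [x + loop for x in range(j, w)]
        mm = [guide[p] != rcs[cols[p]] for p in range(w)]
        m5 = sum(mm[1:12])
        m3 = sum(mm[12:])
        cleav_ok = not (mm[9] or mm[10])
        if (
            loop <= max_loop
            and cleav_ok
            and m3 <= MAX_3P
            and m5 + m3 <= MAX_TOTAL
            and (m5 <= MAX_5P or (m5 <= MAX_5P_COMP and m3 == 0 and loop == 0))
        ):
            return True
    return False


def mirna_hit_exists(guide: str, tran: str, max_loop: int = MAX_LOOP) -> bool:
    """Exhaustive site scan for one guide on the sense transcript.

    The 5' region (guide positions 2-12) aligns to the same target columns
    for every loop placement, so a seed-region mismatch count > 2 is an
    exact impossibility filter; surviving offsets get the full exhaustive
    alignment enumeration.
    """
    w = len(guide)
    n = len(tran)
    if n < w:
        return False
    rct = rc(tran)
    R = _enc(rct)
    seed = _enc(guide[1:12])
    seed_wins = np.lib.stride_tricks.sliding_window_view(R, 11)
    seed_mm = (seed_wins != seed).sum(axis=1)  # offset o -> mismatches at rct[o:o+11]
    for loop in range(0, max_loop + 1):
        sl = w + loop
        n_off = n - sl + 1
        if n_off <= 0:
            continue
        # guide positions 2-12 pair with rct[o+1 : o+12] for every split,
        # so offsets failing the seed budget can be skipped wholesale
        for o in np.flatnonzero(seed_mm[1 : n_off + 1] <= MAX_TOTAL):
            if duplex_functional(guide, rc(rct[o : o + sl]), max_loop):
                return True
    return False


def fragment_clean(
    frag: str,
    offtarget_seqs: list[str],
    w: int = 21,
    min_mm: int = 3,
    mirna: bool = True,
    both: bool = True,
) -> bool:
    """Brute-force re-verification of a whole fragment: every window must
    be at Hamming distance >= min_mm from every off-target k-mer, and no
    window may have a functional miRNA-like site on any off-target."""
    for ot in offtarget_seqs:
        counts = scan_counts_brute(frag, ot, w, both)
        if (counts < min_mm).any():
            return False
        if mirna:
            for i in range(len(frag) - w + 1):
                km = frag[i : i + w]
                guides = [rc(km)] + ([km] if both else [])
                for g in guides:
                    if mirna_hit_exists(g, ot):
                        return False
    return True
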