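"""miRNA-like trigger rules: the secondary off-target filter.

An siRNA with one or two mismatches to a transcript can still down-regulate
it by acting like a plant miRNA.  The empirically derived target-recognition
rules implemented here: pairing in the 5' part of the small RNA (positions
2-12, numbered from its 5' end) is critical and tolerates at most one
mismatch, including the presumptive cleavage site opposite positions 10-11
which must pair; the 3' part tolerates a mismatch loop of at most two
nucleotides, and a perfectly paired 3' part compensates up to two 5'
mismatches.  Position 1 is not part of the pairing budget.

Geometry: a guide ``g`` (DNA alphabet, written 5'->3') recognizes a target
site ``s`` (sense DNA) when ``g`` matches ``revcomp(s)`` position for
position; a 3' "mismatch loop" is modeled as 1-2 unpaired target
nucleotides inserted between two guide positions of the 3' region
(target-side insertions only; guide-side bulges are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import encode, revcomp

__all__ = [
    "MirnaRuleConfig",
    "DuplexEvaluation",
    "evaluate_duplex",
    "find_mirna_like_sites",
    "screen_fragment_windows",
]


@dataclass(frozen=True)
class MirnaRuleConfig:
    """Tunable boundaries of the miRNA target-recognition rules.

    Positions are 1-based on the guide strand, 5'->3'.  Defaults encode
    the published rule set; ``count_gu_as_match`` relaxes G:U wobble pairs
    to matches (off by default: the source rules never mention wobble).
    """

    five_prime_region: tuple[int, int] = (2, 12)
    cleavage_positions: tuple[int, int] = (10, 11)
    max_5p_mismatch: int = 1
    max_5p_mismatch_if_3p_perfect: int = 2
    max_3p_mismatch: int = 2
    max_total_mismatch: int = 2
    max_3p_loop_nt: int = 2
    count_gu_as_match: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.five_prime_region
        clo, chi = self.cleavage_positions
        if not (1 <= lo <= hi):
            raise ValueError("five_prime_region must be a 1-based (low, high) range")
        if not (lo <= clo <= chi <= hi):
            raise ValueError("cleavage_positions must lie within the 5' region")


@dataclass(frozen=True)
class DuplexEvaluation:
    """One guide / target-site pairing scored under the rules.

    ``functional`` is a pure function of the mismatch counts, the loop
    length, the cleavage-site pairing and the config.
    """

    sirna: str
    site: str
    mismatches_5p: int
    mismatches_3p: int
    loop_len_3p: int
    cleavage_paired: bool
    functional: bool
    reason: str
    #: 1-based guide position after which the 3' loop sits (None if no loop)
    loop_after: int | None = None
    # scan-hit coordinates (filled by find_mirna_like_sites)
    target_id: str = ""
    target_start: int | None = None  # 0-based half-open on the sense target
    target_end: int | None = None
    strand: str = "+"


def _region_indices(cfg: MirnaRuleConfig, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = cfg.five_prime_region
    if hi >= w:
        raise ValueError(f"five_prime_region {cfg.five_prime_region} does not fit a {w}-nt guide")
    idx5 = np.arange(lo - 1, hi)
    idx3 = np.arange(hi, w)  # 3' region: everything past the 5' region
    cleav = np.array(cfg.cleavage_positions) - 1
    return idx5, idx3, cleav


def _split_points(cfg: MirnaRuleConfig, w: int) -> range:
    # loop insertion allowed between guide positions j and j+1 inside the
    # 3'-pairing region (after position five_prime_region[1] .. w-1)
    return range(cfg.five_prime_region[1], w)


def _mismatch_matrix(guides: np.ndarray, cols: np.ndarray, cfg: MirnaRuleConfig) -> np.ndarray:
    """guides: (k, w) codes; cols: (n, w) codes of revcomp-site columns."""
    mism = guides[:, None, :] != cols[None, :, :]
    if cfg.count_gu_as_match:
        # in revcomp space, guide G : target U appears as (G, A) and
        # guide U : target G as (T, C)  [codes A0 C1 G2 T3]
        wob = ((guides[:, None, :] == 2) & (cols[None, :, :] == 0)) | (
            (guides[:, None, :] == 3) & (cols[None, :, :] == 1)
        )
        mism &= ~wob
    return mism


def _rule_verdict(
    cfg: MirnaRuleConfig, m5: int, m3: int, loop: int, cleav_ok: bool
) -> tuple[bool, str]:
    if loop > cfg.max_3p_loop_nt:
        return False, f"3' loop of {loop} nt exceeds maximum {cfg.max_3p_loop_nt}"
    if not cleav_ok:
        return False, "mismatch at the cleavage site (positions 10-11)"
    if m3 > cfg.max_3p_mismatch:
        return False, f"{m3} mismatches in the 3' region exceed {cfg.max_3p_mismatch}"
    if m5 + m3 > cfg.max_total_mismatch:
        return False, (
            f"{m5 + m3} substitution mismatches in total exceed "
            f"{cfg.max_total_mismatch}"
        )
    if m5 <= cfg.max_5p_mismatch:
        return True, "functional: 5' pairing within tolerance"
    if m5 <= cfg.max_5p_mismatch_if_3p_perfect and m3 == 0 and loop == 0:
        return True, "functional: perfect 3' pairing compensates two 5' mismatches"
    return False, f"{m5} mismatches in the 5' region (positions 2-12)"


def evaluate_duplex(
    sirna: str,
    site: str,
    config: MirnaRuleConfig | None = None,
) -> DuplexEvaluation:
    """Score one guide against one target site.

    ``site`` is the sense-strand target subsequence; its length may exceed
    the guide length by the loop size (extra nucleotides bulge out of the
    duplex in the 3'-pairing region).  Every admissible loop placement is
    tried and the most favorable one is reported (functional if any
    placement is functional; otherwise fewest total mismatches).  Sites
    with loops longer than the tolerated maximum are reported as
    non-functional rather than rejected.
    """
    cfg = config or MirnaRuleConfig()
    sirna = sirna.upper()
    site = site.upper()
    w = len(sirna)
    loop = len(site) - w
    if loop < 0:
        raise ValueError(
            f"site ({len(site)} nt) shorter than the guide ({w} nt); "
            "guide-side bulges are not modeled"
        )
    idx5, idx3, cleav = _region_indices(cfg, w)
    g = encode(sirna)[None, :]
    rc = encode(revcomp(site))
    splits = [None] if loop == 0 else list(_split_points(cfg, w))
    best: DuplexEvaluation | None = None
    for j in splits:
        if j is None:
            colidx = np.arange(w)
        else:
            colidx = np.concatenate([np.arange(j), np.arange(j, w) + loop])
        mism = _mismatch_matrix(g, rc[colidx][None, :], cfg)[0, 0]
        m5 = int(mism[idx5].sum())
        m3 = int(mism[idx3].sum())
        cleav_ok = not mism[cleav].any()
        functional, reason = _rule_verdict(cfg, m5, m3, loop, cleav_ok)
        ev = DuplexEvaluation(
            sirna, site, m5, m3, loop, cleav_ok, functional, reason, loop_after=j
        )
        if best is None or _better(ev, best):
            best = ev
    assert best is not None
    return best


def _better(a: DuplexEvaluation, b: DuplexEvaluation) -> bool:
    ka = (not a.functional, a.mismatches_5p + a.mismatches_3p)
    kb = (not b.functional, b.mismatches_5p + b.mismatches_3p)
    return ka < kb


def find_mirna_like_sites(
    sirna: str,
    target: str,
    config: MirnaRuleConfig | None = None,
    *,
    target_id: str = "target",
    scan_antisense: bool = False,
) -> list[DuplexEvaluation]:
    """All functional miRNA-like sites of one guide on a target transcript.

    Scans every target offset and every admissible 3'-loop placement
    (loops of 0..max nt).  One hit is reported per (strand, site span):
    the most favorable placement.  ``scan_antisense`` additionally scans
    the reverse complement of the target.
    """
    cfg = config or MirnaRuleConfig()
    hits = _scan_guides(
        np.asarray(encode(sirna.upper()))[None, :], target.upper(), cfg
    )
    out = []
    for _, start, end, m5, m3, loop, j, strand_flip in hits:
        out.append(
            DuplexEvaluation(
                sirna.upper(),
                target[start:end].upper(),
                m5,
                m3,
                loop,
                True,
                True,
                "functional miRNA-like pairing",
                loop_after=j,
                target_id=target_id,
                target_start=start,
                target_end=end,
                strand="+",
            )
        )
    if scan_antisense:
        n = len(target)
        for _, start, end, m5, m3, loop, j, _ in _scan_guides(
            np.asarray(encode(sirna.upper()))[None, :], revcomp(target), cfg
        ):
            out.append(
                DuplexEvaluation(
                    sirna.upper(),
                    revcomp(target[n - end : n - start]).upper(),
                    m5,
                    m3,
                    loop,
                    True,
                    True,
                    "functional miRNA-like pairing",
                    loop_after=j,
                    target_id=target_id,
                    target_start=n - end,
                    target_end=n - start,
                    strand="-",
                )
            )
    return out


def _scan_guides(
    guides: np.ndarray, target: str, cfg: MirnaRuleConfig
) -> list[tuple[int, int, int, int, int, int, int | None, bool]]:
    """Vectorized scan of (k, w) guide codes against a sense target.

    Returns functional hits as tuples
    (guide_index, site_start, site_end, m5, m3, loop, loop_after, False)
    with site coordinates 0-based half-open on the sense target, one per
    (guide, site span) keeping the most favorable placement.
    """
    k, w = guides.shape
    n = len(target)
    if n < w:
        return []
    idx5, idx3, cleav = _region_indices(cfg, w)
    rc = encode(revcomp(target))
    best: dict[tuple[int, int, int], tuple[int, int, int | None]] = {}
    for loop in range(0, cfg.max_3p_loop_nt + 1):
        site_len = w + loop
        if n < site_len:
            break
        windows = np.lib.stride_tricks.sliding_window_view(rc, site_len)
        splits = [None] if loop == 0 else list(_split_points(cfg, w))
        for j in splits:
            if j is None:
                colidx = np.arange(w)
            else:
                colidx = np.concatenate([np.arange(j), np.arange(j, w) + loop])
            sub = windows[:, colidx]
            mism = _mismatch_matrix(guides, sub, cfg)
            m5 = mism[:, :, idx5].sum(axis=2)
            m3 = mism[:, :, idx3].sum(axis=2)
            cleav_ok = ~mism[:, :, cleav].any(axis=2)
            func = (
                cleav_ok
                & (m3 <= cfg.max_3p_mismatch)
                & (m5 + m3 <= cfg.max_total_mismatch)
                & (
                    (m5 <= cfg.max_5p_mismatch)
                    | (
                        (m5 <= cfg.max_5p_mismatch_if_3p_perfect)
                        & (m3 == 0)
                        & (loop == 0)
                    )
                )
            )
            for gi, o_rc in zip(*np.nonzero(func)):
                start = n - int(o_rc) - site_len
                key = (int(gi), start, site_len)
                cand = (int(m5[gi, o_rc]), int(m3[gi, o_rc]), j)
                if key not in best or cand[:2] < best[key][:2]:
                    best[key] = cand
    return [
        (gi, start, start + site_len, m5v, m3v, site_len - w, j, False)
        for (gi, start, site_len), (m5v, m3v, j) in sorted(best.items())
    ]


def screen_fragment_windows(
    fragment: str,
    transcript: str,
    window_starts: "np.ndarray | list[int]",
    config: MirnaRuleConfig | None = None,
    *,
    window_len: int = 21,
    both_strands: bool = True,
) -> dict[int, int]:
    """Count functional miRNA-like sites per fragment window on one
    off-target transcript (batched; used by the fragment search).

    For each fragment window k-mer, the antisense siRNA (revcomp of the
    k-mer) is scanned against the transcript; with ``both_strands`` the
    sense-polarity siRNA (the k-mer itself, which recognizes
    revcomp-like sites on the message) is scanned too.  Returns
    ``{window_start: hit count}`` for starts with at least one hit.
    """
    cfg = config or MirnaRuleConfig()
    starts = [int(s) for s in window_starts]
    if not starts:
        return {}
    fragment = fragment.upper()
    kmers = np.stack([encode(fragment[s : s + window_len]) for s in starts])
    antisense = np.stack(
        [encode(revcomp(fragment[s : s + window_len])) for s in starts]
    )
    counts: dict[int, int] = {}
    for guides in (antisense,) if not both_strands else (antisense, kmers):
        for gi, *_ in _scan_guides(guides, transcript.upper(), cfg):
            counts[starts[gi]] = counts.get(starts[gi], 0) + 1
    return counts
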