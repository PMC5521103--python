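"""Sliding-window mismatch computation.

Two modes cover the two questions the method asks of a candidate fragment:

* **aligned mode** (:func:`window_mismatches_aligned`) globally aligns the
  fragment to its corresponding region of a comparator gene and counts,
  for every run of ``window_len`` consecutive fragment nucleotides, the
  substitution and gap columns falling inside that run.  This reproduces
  the alignment-report style of analysis (underlined 21-bp stretches with
  their mismatch counts) and feeds the mismatch-site tabulation.

* **scan mode** (:func:`min_distance_scan`) asks the sharper question that
  actually governs silencing risk: for every fragment k-mer, the minimum
  Hamming distance to *any* k-mer of a transcript, on both strands if
  requested.  siRNAs can pair with any register of an off-target message,
  not only the aligned one, so scan mode is the authoritative specificity
  check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import _make_aligner, encode, revcomp

__all__ = [
    "WindowProfile",
    "window_mismatches_aligned",
    "min_distance_scan",
    "tabulate_mismatch_sites",
    "mismatch_site_table",
    "profile_to_tsv",
    "render_alignment_report",
]


@dataclass
class WindowProfile:
    """Per-window mismatch counts of a fragment against one comparator.

    ``counts[i]`` is the mismatch count of the window starting at fragment
    position ``i`` (0-based).  In aligned mode it is the number of
    substitution + gap columns of the global alignment that intersect the
    window; in scan mode it is the minimum Hamming distance of the window
    k-mer over all comparator k-mers (both strands when enabled).
    """

    fragment_id: str
    comparator_id: str
    window_len: int
    counts: np.ndarray
    mode: str  # "aligned" | "scan"
    note: str = ""
    #: aligned mode only: fragment-coordinate span (lo, hi) inclusive of
    #: each mismatch column (substitutions/deletions: lo == hi; comparator
    #: insertions sit between two fragment positions: hi == lo + 1)
    mismatch_spans: list[tuple[int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_windows(self) -> int:
        return int(self.counts.size)


def _align_columns(fragment: str, comparator: str) -> tuple[list[tuple[int, int]], str, str]:
    """Globally align and classify columns.

    Returns mismatch-column spans in fragment coordinates plus the two
    gapped alignment strings.
    """
    aligner = _make_aligner()
    aln = aligner.align(fragment, comparator)[0]
    frow, crow = str(aln[0]), str(aln[1])
    spans: list[tuple[int, int]] = []
    fpos = 0  # index of next fragment base
    for fc, cc in zip(frow, crow):
        if fc == "-":
            # comparator insertion: sits between fragment positions
            # fpos-1 and fpos; counted for windows covering both.  An
            # insertion outside the fragment span touches no window.
            if 0 < fpos < len(fragment):
                spans.append((fpos - 1, fpos))
        else:
            if cc == "-" or cc != fc:
                spans.append((fpos, fpos))
            fpos += 1
    return spans, frow, crow


def window_mismatches_aligned(
    fragment: str,
    comparator_region: str,
    *,
    window_len: int = 21,
    fragment_id: str = "fragment",
    comparator_id: str = "comparator",
) -> WindowProfile:
    """Count mismatch columns per 21-bp window over a global alignment.

    Windows are anchored on the fragment: window ``i`` covers fragment
    positions ``[i, i + window_len)``.  Gap columns count as mismatches
    (the conservative choice for silencing risk).
    """
    fragment = fragment.upper()
    comparator_region = comparator_region.upper()
    if not fragment or not comparator_region:
        raise ValueError("fragment and comparator region must be non-empty")
    if len(fragment) < window_len:
        return WindowProfile(
            fragment_id,
            comparator_id,
            window_len,
            np.zeros(0, dtype=np.int64),
            "aligned",
            note=f"fragment ({len(fragment)} nt) shorter than window ({window_len} nt)",
            mismatch_spans=[],
        )
    spans, _, _ = _align_columns(fragment, comparator_region)
    n_win = len(fragment) - window_len + 1
    counts = np.zeros(n_win, dtype=np.int64)
    for lo, hi in spans:
        # windows i with [i, i + w - 1] covering the whole span [lo, hi]
        first = max(0, hi - window_len + 1)
        last = min(n_win - 1, lo)
        if first <= last:
            counts[first : last + 1] += 1
    return WindowProfile(
        fragment_id, comparator_id, window_len, counts, "aligned", mismatch_spans=spans
    )


def _scan_min_counts(frag: np.ndarray, tran: np.ndarray, w: int) -> np.ndarray:
    """Minimum Hamming distance of each fragment w-mer over all transcript
    w-mers, computed by windowed sums of the full mismatch matrix."""
    n_wf = frag.size - w + 1
    n_wt = tran.size - w + 1
    mism = (frag[:, None] != tran[None, :]).astype(np.int32)
    acc = np.zeros((n_wf, n_wt), dtype=np.int32)
    for k in range(w):
        acc += mism[k : k + n_wf, k : k + n_wt]
    return acc.min(axis=1)


def min_distance_scan(
    fragment: str,
    transcript: str,
    both_strands: bool = True,
    *,
    window_len: int = 21,
    fragment_id: str = "fragment",
    comparator_id: str = "transcript",
) -> WindowProfile:
    """k-mer scan: minimum Hamming distance of every fragment window over
    all transcript windows (and the reverse-complement strand if enabled).
    """
    fragment = fragment.upper()
    transcript = transcript.upper()
    if len(fragment) < window_len:
        return WindowProfile(
            fragment_id,
            comparator_id,
            window_len,
            np.zeros(0, dtype=np.int64),
            "scan",
            note=f"fragment ({len(fragment)} nt) shorter than window ({window_len} nt)",
        )
    n_win = len(fragment) - window_len + 1
    if len(transcript) < window_len:
        warnings.warn(
            f"transcript {comparator_id!r} shorter than window length; "
            "no k-mers to compare against",
            stacklevel=2,
        )
        return WindowProfile(
            fragment_id,
            comparator_id,
            window_len,
            np.full(n_win, window_len, dtype=np.int64),
            "scan",
            note="transcript shorter than window length",
        )
    frag = encode(fragment)
    counts = _scan_min_counts(frag, encode(transcript), window_len)
    if both_strands:
        counts = np.minimum(
            counts, _scan_min_counts(frag, encode(revcomp(transcript)), window_len)
        )
    return WindowProfile(fragment_id, comparator_id, window_len, counts, "scan")


def tabulate_mismatch_sites(profile: WindowProfile, k: int) -> int:
    """Count mismatch *sites* with exactly ``k`` mismatches per window.

    Windows whose count equals ``k`` are grouped into maximal runs of
    consecutive starts; within a run, windows sharing at least one common
    mismatch column collapse into one site (walked greedily left to
    right).  This mimics tabulating discrete underlined stretches of an
    alignment report; the raw per-window counts remain available on the
    profile.
    """
    if k < 0 or k > profile.window_len:
        raise ValueError(f"k must be in [0, {profile.window_len}]")
    if profile.mode != "aligned" or profile.mismatch_spans is None:
        raise ValueError("site tabulation requires an aligned-mode profile")
    w = profile.window_len
    starts = np.flatnonzero(profile.counts == k)
    if starts.size == 0:
        return 0

    def cols_of(i: int) -> frozenset[int]:
        return frozenset(
            c
            for c, (lo, hi) in enumerate(profile.mismatch_spans)
            if lo <= i + w - 1 and hi >= i
        )

    sites = 0
    prev = None
    shared: frozenset[int] = frozenset()
    for i in starts:
        cols = cols_of(int(i))
        if prev is None or i != prev + 1 or not (shared & cols):
            sites += 1
            shared = cols
        else:
            shared &= cols
        prev = i
    return sites


def mismatch_site_table(
    fragment: str,
    comparators: dict[str, str],
    *,
    window_len: int = 21,
    ks: tuple[int, ...] = (1, 2),
    fragment_id: str = "fragment",
) -> pd.DataFrame:
    """Tabulate per-comparator mismatch-site counts at the given k values
    (rows: comparators; columns: ``k=1``, ``k=2``, ...)."""
    rows = {}
    for cid, seq in comparators.items():
        prof = window_mismatches_aligned(
            fragment, seq, window_len=window_len, fragment_id=fragment_id, comparator_id=cid
        )
        rows[cid] = {f"k={k}": tabulate_mismatch_sites(prof, k) for k in ks}
    return pd.DataFrame.from_dict(rows, orient="index")


def profile_to_tsv(profile: WindowProfile) -> pd.DataFrame:
    """Per-window table (window starts reported 1-based, inclusive)."""
    return pd.DataFrame(
        {
            "fragment_id": profile.fragment_id,
            "comparator_id": profile.comparator_id,
            "window_start_1based": np.arange(1, profile.n_windows + 1),
            "mismatches": profile.counts,
        }
    )


def render_alignment_report(
    fragment: str,
    comparator_region: str,
    *,
    window_len: int = 21,
    fragment_id: str = "fragment",
    comparator_id: str = "comparator",
    highlight_max: int = 2,
    block: int = 60,
) -> str:
    """Plain-text alignment report in the underlined-stretch style.

    Blocks of the global alignment with a 1-based position ruler, a match
    line, and per-window annotations: maximal stretches whose windows all
    have <= ``highlight_max`` mismatches are listed beneath with their
    counts (the regions a designer must treat as silencing-competent).
    """
    profile = window_mismatches_aligned(
        fragment,
        comparator_region,
        window_len=window_len,
        fragment_id=fragment_id,
        comparator_id=comparator_id,
    )
    spans, frow, crow = _align_columns(fragment.upper(), comparator_region.upper())
    match_line = "".join(
        "|" if f == c and f != "-" else " " for f, c in zip(frow, crow)
    )
    lines = [f"# {fragment_id} vs {comparator_id} (window {window_len} nt)"]
    for off in range(0, len(frow), block):
        chunk = slice(off, off + block)
        lines.append(f"{'':>12}{_ruler(off + 1, len(frow[chunk]))}")
        lines.append(f"{fragment_id[:10]:>10}  {frow[chunk]}")
        lines.append(f"{'':>10}  {match_line[chunk]}")
        lines.append(f"{comparator_id[:10]:>10}  {crow[chunk]}")
        lines.append("")
    lines.append("# silencing-competent stretches (window mismatch count <= "
                 f"{highlight_max}; positions 1-based on {fragment_id})")
    any_hit = False
    for start, end, cmin, cmax in _low_count_stretches(profile, highlight_max):
        any_hit = True
        lines.append(
            f"  {start + 1}-{end + window_len}  windows with "
            f"{cmin}-{cmax} mismatches"
        )
    if not any_hit:
        lines.append(
            f"  none: every {window_len}-bp window has more than "
            f"{highlight_max} mismatches"
        )
    return "\n".join(lines)


def _ruler(first: int, width: int) -> str:
    marks = [" "] * width
    for pos in range(first, first + width):
        if pos % 10 == 0:
            label = str(pos)
            at = pos - first
            lo = at - len(label) + 1
            if lo >= 0:
                for j, ch in enumerate(label):
                    marks[lo + j] = ch
    return "".join(marks)


def _low_count_stretches(profile: WindowProfile, k_max: int):
    ok = profile.counts <= k_max
    i = 0
    n = profile.n_windows
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            seg = profile.counts[i : j + 1]
            yield i, j, int(seg.min()), int(seg.max())
            i = j + 1
        else:
            i += 1
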