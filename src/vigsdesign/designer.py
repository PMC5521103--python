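"""Search for family-member-specific VIGS fragments.

A fragment qualifies when, against every off-target, *every* one of its
21-bp windows carries at least ``min_mismatch`` (default 3) mismatches in
the k-mer scan sense, and no window could act as a functional miRNA-like
trigger on an off-target; and when it shares at least one perfect window
with every intended co-target (the efficacy side).  The search builds a
per-window validity mask over the source gene, enumerates maximal runs of
valid windows, and returns the maximal fragments those runs support,
ranked by specificity margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import DesignConstraints, GeneFamily, GeneRecord, Role
from .mirna import MirnaRuleConfig, screen_fragment_windows
from .windows import min_distance_scan

__all__ = [
    "Verdict",
    "SpecificityResult",
    "EfficacyResult",
    "FragmentCandidate",
    "ValidityMask",
    "SearchResult",
    "specificity_verdict",
    "efficacy_verdict",
    "evaluate_fragment",
    "search_fragments",
    "longest_shared_stretch",
]

#: below window-length identity, a shared stretch this long has still been
#: associated with partial (~15%) knockdown of homologues
WEAK_SILENCING_MIN_NT = 11


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"


@dataclass
class SpecificityResult:
    passed: bool
    per_offtarget_min: dict[str, int]
    violations: list[str] = field(default_factory=list)
    notice: str = ""


@dataclass
class EfficacyResult:
    passed: bool
    coverage: float  #: fraction of fragment windows exactly matching the target
    longest_shared_nt: int
    warning: str = ""


@dataclass
class FragmentCandidate:
    """A proposed VIGS fragment with its screening evidence."""

    source_id: str
    start: int  # 0-based half-open on the source gene
    end: int
    seq: str
    per_offtarget_min: dict[str, int]
    mirna_hits: int
    intended_coverage: dict[str, float]
    verdict: Verdict
    fail_reasons: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def specificity_margin(self) -> int:
        """Minimum over off-targets of the per-window minimum mismatch count."""
        if not self.per_offtarget_min:
            return 10**6
        return min(self.per_offtarget_min.values())


@dataclass
class ValidityMask:
    """Per window start of the source gene: does the window pass all
    off-target constraints?  A fragment [s, e) is specificity-valid iff
    the mask is true at every start in [s, e - window_len]."""

    source_id: str
    window_len: int
    valid: np.ndarray
    reasons: list[str | None]


@dataclass
class SearchResult:
    """Ranked candidates plus, when empty, per-run diagnostics naming the
    constraint that ended each maximal run of valid windows."""

    candidates: list[FragmentCandidate]
    diagnostics: list[str]
    mask: ValidityMask

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


def specificity_verdict(
    fragment: str,
    offtargets: list[GeneRecord],
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
) -> SpecificityResult:
    """Screen one fragment against a set of off-target genes.

    PASS iff every fragment window has scan-mode mismatch count >=
    ``min_mismatch`` against every off-target and (when enabled) no
    fragment k-mer has a functional miRNA-like site in any off-target.
    """
    cfg = constraints or DesignConstraints()
    fragment = fragment.upper()
    if len(fragment) < cfg.window_len:
        raise ValueError("fragment shorter than the window length")
    if not offtargets:
        return SpecificityResult(
            True, {}, notice="no off-targets supplied; specificity is vacuous"
        )
    per_min: dict[str, int] = {}
    violations: list[str] = []
    for ot in offtargets:
        prof = min_distance_scan(
            fragment,
            ot.seq,
            cfg.both_strands,
            window_len=cfg.window_len,
            comparator_id=ot.id,
        )
        per_min[ot.id] = int(prof.counts.min())
        for i in np.flatnonzero(prof.counts < cfg.min_mismatch):
            violations.append(
                f"window {int(i) + 1}: only {int(prof.counts[i])} mismatch(es) "
                f"within {cfg.window_len} bp against {ot.id}"
            )
        if cfg.apply_mirna_rules:
            hits = screen_fragment_windows(
                fragment,
                ot.seq,
                np.arange(len(fragment) - cfg.window_len + 1),
                mirna_config,
                window_len=cfg.window_len,
                both_strands=cfg.both_strands,
            )
            for start, n_hits in sorted(hits.items()):
                violations.append(
                    f"window {start + 1}: miRNA-like site in {ot.id} "
                    f"({n_hits} functional pairing{'s' if n_hits > 1 else ''})"
                )
    return SpecificityResult(not violations, per_min, violations)


def longest_shared_stretch(a: str, b: str, both_strands: bool = True) -> int:
    """Length of the longest identical substring shared by two sequences
    (optionally also against the reverse complement of ``b``)."""
    from .core import encode, revcomp

    def _lcs(x: np.ndarray, y: np.ndarray) -> int:
        run = np.zeros(y.size, dtype=np.int32)
        best = 0
        for xi in x:
            eq = y == xi
            prev = np.concatenate(([0], run[:-1]))
            run = np.where(eq, prev + 1, 0)
            m = int(run.max(initial=0))
            if m > best:
                best = m
        return best

    xa = encode(a.upper())
    best = _lcs(xa, encode(b.upper()))
    if both_strands:
        best = max(best, _lcs(xa, encode(revcomp(b))))
    return best


def efficacy_verdict(
    fragment: str,
    intended: GeneRecord,
    constraints: DesignConstraints | None = None,
    min_zero_windows: int = 1,
) -> EfficacyResult:
    """Check that a fragment can silence an intended (co-)target.

    PASS iff at least ``min_zero_windows`` fragment windows match the
    target with zero mismatches; coverage is the fraction of such windows.
    A shared identical stretch of 11..window_len-1 nt triggers a weak
    partial-silencing warning whatever the verdict.
    """
    cfg = constraints or DesignConstraints()
    fragment = fragment.upper()
    if len(fragment) < cfg.window_len:
        raise ValueError("fragment shorter than the window length")
    prof = min_distance_scan(
        fragment,
        intended.seq,
        cfg.both_strands,
        window_len=cfg.window_len,
        comparator_id=intended.id,
    )
    zero = int((prof.counts == 0).sum())
    coverage = zero / prof.n_windows
    passed = zero >= min_zero_windows
    warning = ""
    shared = longest_shared_stretch(fragment, intended.seq, cfg.both_strands)
    if WEAK_SILENCING_MIN_NT <= shared < cfg.window_len:
        warning = (
            f"longest identical stretch with {intended.id} is only {shared} nt "
            f"(< {cfg.window_len}); partial (~15%) knockdown has been reported "
            "for stretches this short"
        )
    return EfficacyResult(passed, coverage, shared, warning)


def evaluate_fragment(
    source: GeneRecord,
    start: int,
    end: int,
    family: GeneFamily,
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
) -> FragmentCandidate:
    """Fully screen the fragment source[start:end] and return a candidate
    with verdict and diagnostics (usable on any span, not only search hits)."""
    cfg = constraints or DesignConstraints()
    frag = source.seq[start:end]
    offtargets = [m for m in family.by_role(Role.OFFTARGET) if m.id != source.id]
    intended = family.by_role(Role.INTENDED) or [source]
    spec = specificity_verdict(frag, offtargets, cfg, mirna_config)
    reasons = list(spec.violations)
    coverage: dict[str, float] = {}
    for member in intended:
        eff = efficacy_verdict(frag, member, cfg)
        coverage[member.id] = eff.coverage
        if not eff.passed:
            reasons.append(f"no zero-mismatch window against intended target {member.id}")
            if eff.warning:
                reasons.append(eff.warning)
    mirna_hits = sum(
        1 for v in spec.violations if "miRNA-like" in v
    )
    return FragmentCandidate(
        source_id=source.id,
        start=start,
        end=end,
        seq=frag,
        per_offtarget_min=spec.per_offtarget_min,
        mirna_hits=mirna_hits,
        intended_coverage=coverage,
        verdict=Verdict.PASS if not reasons else Verdict.FAIL,
        fail_reasons=reasons,
    )


def build_validity_mask(
    source: GeneRecord,
    offtargets: list[GeneRecord],
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
) -> ValidityMask:
    """Per-window validity of the source gene against all off-targets.

    The Hamming criterion is evaluated for every window; the (more
    expensive) miRNA-like-site screen only for windows that survive it,
    since it can only invalidate further windows.
    """
    cfg = constraints or DesignConstraints()
    w = cfg.window_len
    n_win = len(source.seq) - w + 1
    valid = np.ones(n_win, dtype=bool)
    reasons: list[str | None] = [None] * n_win
    for ot in offtargets:
        prof = min_distance_scan(
            source.seq, ot.seq, cfg.both_strands, window_len=w, comparator_id=ot.id
        )
        for i in np.flatnonzero(prof.counts < cfg.min_mismatch):
            i = int(i)
            if valid[i]:
                valid[i] = False
                reasons[i] = (
                    f"only {int(prof.counts[i])} mismatch(es) within {w} bp "
                    f"against {ot.id}"
                )
    if cfg.apply_mirna_rules:
        surviving = np.flatnonzero(valid)
        for ot in offtargets:
            if surviving.size == 0:
                break
            hits = screen_fragment_windows(
                source.seq,
                ot.seq,
                surviving,
                mirna_config,
                window_len=w,
                both_strands=cfg.both_strands,
            )
            for start in hits:
                if valid[start]:
                    valid[start] = False
                    reasons[start] = f"miRNA-like site in {ot.id}"
            surviving = np.flatnonzero(valid)
    return ValidityMask(source.id, w, valid, reasons)


def search_fragments(
    source: GeneRecord,
    family: GeneFamily,
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
) -> SearchResult:
    """Find all maximal qualifying fragments of ``source``.

    Candidates are ranked by (1) specificity margin (minimum over
    off-targets of the per-window minimum mismatch count), descending;
    (2) mean coverage of the intended targets, descending; (3) leftmost
    start.  An empty result carries diagnostics naming, for each maximal
    run of valid windows, the constraint that ended it.
    """
    cfg = constraints or DesignConstraints()
    w = cfg.window_len
    if len(source.seq) < cfg.min_fragment_len:
        raise ValueError(
            f"source {source.id!r} ({len(source.seq)} nt) is shorter than "
            f"min_fragment_len ({cfg.min_fragment_len} nt)"
        )
    offtargets = [m for m in family.by_role(Role.OFFTARGET) if m.id != source.id]
    intended = family.by_role(Role.INTENDED) or [source]
    mask = build_validity_mask(source, offtargets, cfg, mirna_config)
    candidates: list[FragmentCandidate] = []
    diagnostics: list[str] = []
    n_win = mask.valid.size
    i = 0
    while i < n_win:
        if not mask.valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and mask.valid[j + 1]:
            j += 1
        run_len = j - i + 1
        avail = run_len + w - 1
        ended_by = (
            "end of sequence" if j + 1 >= n_win else f"window {j + 2}: {mask.reasons[j + 1]}"
        )
        if avail < cfg.min_fragment_len:
            diagnostics.append(
                f"run of valid windows at {i + 1}-{j + 1} supports at most "
                f"{avail} nt < min_fragment_len {cfg.min_fragment_len}; "
                f"run ended by {ended_by}"
            )
        else:
            start, end = i, i + min(avail, cfg.max_fragment_len)
            frag = source.seq[start:end]
            per_min = {
                ot.id: int(
                    min_distance_scan(
                        frag, ot.seq, cfg.both_strands, window_len=w
                    ).counts.min()
                )
                for ot in offtargets
            }
            coverage: dict[str, float] = {}
            eff_fail = []
            for member in intended:
                eff = efficacy_verdict(frag, member, cfg)
                coverage[member.id] = eff.coverage
                if not eff.passed:
                    eff_fail.append(member.id)
            if eff_fail:
                diagnostics.append(
                    f"fragment {start + 1}-{end} passes specificity but has no "
                    f"zero-mismatch window against intended target(s) "
                    f"{', '.join(eff_fail)}"
                )
            else:
                candidates.append(
                    FragmentCandidate(
                        source_id=source.id,
                        start=start,
                        end=end,
                        seq=frag,
                        per_offtarget_min=per_min,
                        mirna_hits=0,
                        intended_coverage=coverage,
                        verdict=Verdict.PASS,
                    )
                )
        i = j + 1
    candidates.sort(
        key=lambda c: (
            -c.specificity_margin,
            -(np.mean(list(c.intended_coverage.values())) if c.intended_coverage else 0.0),
            c.start,
        )
    )
    return SearchResult(candidates, diagnostics, mask)
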