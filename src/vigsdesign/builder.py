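"""Subgroup clustering, chimeric-insert assembly and overlap-extension
primers.

A single short fragment can co-silence the near-identical members of one
subgroup of the family; silencing the whole family therefore takes one
representative fragment per subgroup, concatenated into a single chimeric
insert (assembled in the wet lab by overlap-extension PCR) and carried by
the TRV RNA2 vector.  Concatenation mints novel k-mers across each
junction, so every junction-spanning window is re-screened against the
off-targets before the construct is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import DesignConstraints, GeneFamily, Role, revcomp
from .designer import FragmentCandidate, Verdict
from .mirna import MirnaRuleConfig, screen_fragment_windows
from .windows import min_distance_scan

__all__ = [
    "Subgroup",
    "JunctionReport",
    "Primer",
    "ChimericConstruct",
    "partition_subgroups",
    "build_chimera",
    "design_overlap_primers",
    "wallace_tm",
]


@dataclass(frozen=True)
class Subgroup:
    """One cluster of near-identical family members."""

    label: str
    member_ids: tuple[str, ...]
    representative_id: str


@dataclass
class JunctionReport:
    """Screening outcome of the novel windows spanning one junction."""

    index: int  # junction between fragments[index] and fragments[index+1]
    insert_pos: int  # 0-based position of the first downstream base
    window_starts: tuple[int, int]  # [first, last] novel window start, inclusive
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    tm: float
    half_tms: tuple[float, float] | None = None


@dataclass
class ChimericConstruct:
    fragments: list[FragmentCandidate]
    insert_seq: str
    junctions: list[JunctionReport]
    primers: list[Primer]
    total_len: int
    verdict: Verdict
    warnings: list[str] = field(default_factory=list)


def partition_subgroups(family: GeneFamily, identity_threshold: float) -> list[Subgroup]:
    """Partition the family by single-linkage clustering at a percent-
    identity threshold (an operational stand-in for a phylogenetic tree).

    Two members end up in one subgroup iff they are connected by a chain
    of pairwise identities >= threshold.  The representative of each
    subgroup is the member with the highest mean identity to its
    co-members (first in input order on ties); labels a, b, c, ... follow
    the input order of each subgroup's first member.
    """
    if not 0 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (0, 100]")
    if len(family) == 0:
        raise ValueError("family is empty")
    ids = family.ids
    if len(ids) == 1:
        return [Subgroup("a", (ids[0],), ids[0])]
    ident = family.identity_matrix.to_numpy()
    dist = 100.0 - ident
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="single")
    flat = fcluster(z, t=100.0 - identity_threshold, criterion="distance")
    order: list[int] = []
    for c in flat:
        if c not in order:
            order.append(c)
    subgroups = []
    for rank, cluster_id in enumerate(order):
        members = [i for i, c in enumerate(flat) if c == cluster_id]
        if len(members) == 1:
            rep = members[0]
        else:
            means = [
                np.mean([ident[i, j] for j in members if j != i]) for i in members
            ]
            rep = members[int(np.argmax(means))]
        label = _letters(rank)
        subgroups.append(
            Subgroup(label, tuple(ids[i] for i in members), ids[rep])
        )
    return subgroups


def _letters(rank: int) -> str:
    out = ""
    rank += 1
    while rank:
        rank, r = divmod(rank - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def build_chimera(
    fragments: list[FragmentCandidate],
    family: GeneFamily,
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
    *,
    screen_junctions: bool = True,
    linker: str = "",
    primer_half_len: int = 20,
) -> ChimericConstruct:
    """Concatenate qualifying fragments into one chimeric insert.

    Every fragment must individually carry a PASS verdict.  The
    ``window_len - 1`` novel windows spanning each junction (plus any
    linker) are re-screened against all off-target family members with
    the scan-mode Hamming criterion and the miRNA rules; the construct
    verdict is PASS iff all junctions pass.  The insert length is checked
    against the TRV insert bounds (a warning, not an error, when
    violated).  Junction screening can be disabled for strict emulation
    of designs that skip it.
    """
    cfg = constraints or DesignConstraints()
    w = cfg.window_len
    if not fragments:
        raise ValueError("no fragments supplied")
    for f in fragments:
        if f.verdict is not Verdict.PASS:
            shown = f.fail_reasons[:3]
            more = len(f.fail_reasons) - len(shown)
            detail = "; ".join(shown) + (f"; ... +{more} more" if more > 0 else "")
            raise ValueError(
                f"fragment {f.source_id}[{f.start}:{f.end}] has verdict "
                f"'fail'; only PASS fragments can be assembled ({detail})"
            )
    insert = linker.join(f.seq for f in fragments) if linker else "".join(
        f.seq for f in fragments
    )
    offtargets = [m for m in family.by_role(Role.OFFTARGET)]
    junctions: list[JunctionReport] = []
    pos = 0
    for idx in range(len(fragments) - 1):
        up_end = pos + len(fragments[idx].seq)
        down_start = up_end + len(linker)
        first = max(0, up_end - w + 1)
        last = min(len(insert) - w, down_start - 1)
        rep = JunctionReport(idx, down_start, (first, last))
        if screen_junctions and last >= first:
            jfrag = insert[first : last + w]
            for ot in offtargets:
                prof = min_distance_scan(
                    jfrag, ot.seq, cfg.both_strands, window_len=w, comparator_id=ot.id
                )
                for i in np.flatnonzero(prof.counts < cfg.min_mismatch):
                    rep.violations.append(
                        f"junction window at insert position {first + int(i) + 1}: "
                        f"only {int(prof.counts[i])} mismatch(es) within {w} bp "
                        f"against {ot.id}"
                    )
                if cfg.apply_mirna_rules:
                    hits = screen_fragment_windows(
                        jfrag,
                        ot.seq,
                        np.arange(len(jfrag) - w + 1),
                        mirna_config,
                        window_len=w,
                        both_strands=cfg.both_strands,
                    )
                    for s in sorted(hits):
                        rep.violations.append(
                            f"junction window at insert position {first + s + 1}: "
                            f"miRNA-like site in {ot.id}"
                        )
        junctions.append(rep)
        pos = down_start
    warnings_: list[str] = []
    lo, hi = cfg.insert_len_bounds
    if not lo <= len(insert) <= hi:
        warnings_.append(
            f"insert length {len(insert)} nt outside the TRV insert bounds "
            f"{lo}-{hi} nt"
        )
    verdict = (
        Verdict.PASS if all(j.passed for j in junctions) else Verdict.FAIL
    )
    construct = ChimericConstruct(
        fragments=list(fragments),
        insert_seq=insert,
        junctions=junctions,
        primers=[],
        total_len=len(insert),
        verdict=verdict,
        warnings=warnings_,
    )
    construct.primers = design_overlap_primers(construct, primer_half_len)
    return construct


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def design_overlap_primers(
    construct: ChimericConstruct, primer_half_len: int = 20
) -> list[Primer]:
    """Overlap-extension PCR primers for a chimeric insert.

    Per junction, a bridging oligo made of the last ``primer_half_len`` nt
    of the upstream fragment plus the first ``primer_half_len`` nt of the
    downstream one (and its reverse complement); terminal primers from the
    insert ends.  Melting temperatures by the Wallace rule, reported per
    half and for the whole bridge.
    """
    h = primer_half_len
    for f in construct.fragments:
        if len(f.seq) < h:
            raise ValueError(
                f"fragment {f.source_id}[{f.start}:{f.end}] "
                f"({len(f.seq)} nt) shorter than primer_half_len ({h} nt)"
            )
    insert = construct.insert_seq
    primers = [
        Primer("terminal_fwd", insert[:h], wallace_tm(insert[:h])),
        Primer("terminal_rev", revcomp(insert[-h:]), wallace_tm(insert[-h:])),
    ]
    for idx in range(len(construct.fragments) - 1):
        up = construct.fragments[idx].seq
        down = construct.fragments[idx + 1].seq
        bridge = up[-h:] + down[:h]
        halves = (wallace_tm(up[-h:]), wallace_tm(down[:h]))
        primers.append(
            Primer(f"bridge_{idx + 1}_fwd", bridge, wallace_tm(bridge), halves)
        )
        primers.append(
            Primer(
                f"bridge_{idx + 1}_rev",
                revcomp(bridge),
                wallace_tm(bridge),
                (wallace_tm(down[:h]), wallace_tm(up[-h:])),
            )
        )
    return primers
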