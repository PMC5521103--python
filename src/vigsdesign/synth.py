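"""Deterministic synthetic gene-family generator.

Emulates a small, highly homologous gene family: one ~450-nt ancestral ORF
gives rise to subgroup ancestors by i.i.d. substitution at a
between-subgroup divergence, and each subgroup ancestor to its members at
a within-subgroup divergence (uniform choice among the three alternative
bases, so the expected per-site match probability between two sequences
derived at rate p from a common ancestor is (1-p)^2 + p^2/3).  Defaults
mimic a 12-member family in six subgroups of sizes 3,3,2,2,1,1.

:func:`plant_region` additionally rewrites one region of a chosen member
(by rejection sampling, verified with the scan engine) so that it is
guaranteed to pass the specificity screen against all other members —
the ground-truth "qualifying fragment" used in recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DesignConstraints, GeneFamily, GeneRecord, Role
from .mirna import MirnaRuleConfig, screen_fragment_windows
from .windows import min_distance_scan

__all__ = ["FamilySpec", "PlantSpec", "generate_family", "plant_region"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the synthetic family.

    Divergences are per-site substitution probabilities; indel_rate is the
    per-site probability of an indel event (half deletions, half
    single-base insertions), zero by default because the method's windows
    align without gaps in the regions of interest.
    """

    ancestor_len: int = 450
    n_subgroups: int = 6
    members_per_subgroup: tuple[int, ...] = (3, 3, 2, 2, 1, 1)
    between_divergence: float = 0.15
    within_divergence: float = 0.02
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.members_per_subgroup) != self.n_subgroups:
            raise ValueError("members_per_subgroup must have n_subgroups entries")
        for p in (self.between_divergence, self.within_divergence, self.indel_rate):
            if not 0.0 <= p < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if sum(self.members_per_subgroup) < 2:
            raise ValueError("family must have at least 2 members")


@dataclass(frozen=True)
class PlantSpec:
    """A region to rewrite in one member so it qualifies by construction.

    guarantee
        ``"min_mismatch_ge_3"``: every window of the planted region passes
        the full specificity screen (scan-mode Hamming >= min_mismatch
        and, when the constraints enable it, no functional miRNA-like
        site) against every other member.
        ``"exact_shared_with"``: the identical region is also written into
        the members listed in ``shared_with`` (which are then excluded
        from the specificity guarantee), so efficacy holds for them by
        construction.
    """

    host_member: str
    region_start: int
    region_len: int = 80
    guarantee: str = "min_mismatch_ge_3"
    shared_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.guarantee not in ("min_mismatch_ge_3", "exact_shared_with"):
            raise ValueError(f"unknown guarantee {self.guarantee!r}")
        if self.guarantee == "exact_shared_with" and not self.shared_with:
            raise ValueError("exact_shared_with requires a non-empty shared_with list")


def _mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < p
    if mask.any():
        # uniform choice among the 3 alternative bases
        out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
    return out


def _indel(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    keep = rng.random(codes.size) >= rate / 2.0
    out = list(codes[keep])
    ins_mask = rng.random(len(out)) < rate / 2.0
    for i in np.flatnonzero(ins_mask)[::-1]:
        out.insert(int(i) + 1, int(rng.integers(0, 4)))
    return np.array(out, dtype=codes.dtype)


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def generate_family(spec: FamilySpec) -> tuple[GeneFamily, dict[str, str]]:
    """Generate a family plus ground-truth subgroup labels.

    Returns ``(family, labels)`` where ``labels`` maps member ID to its
    subgroup label ('a', 'b', ...).  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.integers(0, 4, spec.ancestor_len, dtype=np.int8)
    members: list[GeneRecord] = []
    labels: dict[str, str] = {}
    idx = 0
    for sg, size in enumerate(spec.members_per_subgroup):
        sub_anc = _mutate(ancestor, spec.between_divergence, rng)
        for _ in range(size):
            codes = _mutate(sub_anc, spec.within_divergence, rng)
            codes = _indel(codes, spec.indel_rate, rng)
            idx += 1
            mid = f"m{idx:02d}"
            members.append(GeneRecord(mid, _decode(codes)))
            labels[mid] = chr(ord("a") + sg)
    return GeneFamily(members), labels


def _region_qualifies(
    region: str,
    comparators: list[GeneRecord],
    cfg: DesignConstraints,
    mirna_config: MirnaRuleConfig | None,
) -> bool:
    for other in comparators:
        prof = min_distance_scan(
            region, other.seq, cfg.both_strands, window_len=cfg.window_len
        )
        if (prof.counts < cfg.min_mismatch).any():
            return False
        if cfg.apply_mirna_rules:
            hits = screen_fragment_windows(
                region,
                other.seq,
                np.arange(len(region) - cfg.window_len + 1),
                mirna_config,
                window_len=cfg.window_len,
                both_strands=cfg.both_strands,
            )
            if hits:
                return False
    return True


def plant_region(
    family: GeneFamily,
    plant: PlantSpec,
    seed: int,
    constraints: DesignConstraints | None = None,
    mirna_config: MirnaRuleConfig | None = None,
    max_iter: int = 200,
) -> tuple[GeneFamily, tuple[int, int]]:
    """Rewrite the planted region until its guarantee holds.

    Random candidate regions are drawn and re-verified with the scan
    engine until every window of the region passes the specificity screen
    against every non-shared member; the identical region is copied into
    ``shared_with`` members for the ``exact_shared_with`` guarantee.
    Returns the modified family and the (start, end) coordinates
    (0-based half-open) of the planted region in the host member.
    """
    cfg = constraints or DesignConstraints()
    host = family[plant.host_member]
    start, length = plant.region_start, plant.region_len
    end = start + length
    if end > len(host.seq):
        raise ValueError(
            f"planted region [{start}, {end}) does not fit in host "
            f"{host.id!r} ({len(host.seq)} nt)"
        )
    if length < cfg.window_len:
        raise ValueError("planted region shorter than the window length")
    shared = set(plant.shared_with) if plant.guarantee == "exact_shared_with" else set()
    unknown = shared - set(family.ids)
    if unknown:
        raise KeyError(f"shared_with names unknown member(s): {sorted(unknown)}")
    comparators = [
        m for m in family.members if m.id != host.id and m.id not in shared
    ]
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        region = _decode(rng.integers(0, 4, length, dtype=np.int8))
        if _region_qualifies(region, comparators, cfg, mirna_config):
            new_members = []
            for m in family.members:
                if m.id == host.id or m.id in shared:
                    if end > len(m.seq):
                        raise ValueError(
                            f"planted region does not fit in shared member {m.id!r}"
                        )
                    new_seq = m.seq[:start] + region + m.seq[end:]
                    new_members.append(GeneRecord(m.id, new_seq, m.role))
                else:
                    new_members.append(m)
            return GeneFamily(new_members), (start, end)
    raise RuntimeError(
        f"no qualifying region found in {max_iter} draws; the family may be "
        "too similar to the random pool — try a larger region or relaxed "
        "constraints"
    )


# ---------------------------------------------------------------------------
# Constructed single-purpose instances (deterministic, verified on build)

def make_window_rule_instances(
    seed: int = 0,
    constraints: DesignConstraints | None = None,
) -> dict[str, tuple[str, GeneRecord]]:
    """Three constructed (fragment, off-target) instances that separate the
    specificity rules:

    ``two_mismatch``
        the off-target carries a site at Hamming distance exactly 2 from
        one fragment window — silencing-competent, must FAIL;
    ``clean``
        every fragment window has >= 3 mismatches to the off-target and
        no miRNA-like site — must PASS;
    ``mirna_loop``
        every window has >= 3 Hamming mismatches, but one window forms a
        functional miRNA-like site (one 5' mismatch at guide position 6
        plus a 2-nt 3' loop) — must FAIL on the miRNA filter alone.

    Each instance is re-verified during construction with the scan engine
    and redrawn from the seed stream until its defining property holds.
    """
    from .core import revcomp as _rc

    cfg = constraints or DesignConstraints()
    w = cfg.window_len
    rng = np.random.default_rng(seed)

    def _rand(n: int) -> str:
        return _decode(rng.integers(0, 4, n, dtype=np.int8))

    def _clean_pair() -> tuple[str, str]:
        while True:
            frag, ot = _rand(80), _rand(450)
            if _region_qualifies(frag, [GeneRecord("ot", ot)], cfg, None):
                return frag, ot

    out: dict[str, tuple[str, GeneRecord]] = {}

    # (a) plant a 2-mismatch window
    while True:
        frag, ot = _clean_pair()
        kmer = list(frag[30 : 30 + w])
        for pos in rng.choice(w, size=2, replace=False):
            kmer[pos] = _BASES[(int(_BASES.tolist().index(kmer[pos])) + 1) % 4]
        planted = "".join(kmer)
        ot_a = ot[:200] + planted + ot[200 + w :]
        prof = min_distance_scan(frag, ot_a, cfg.both_strands, window_len=w)
        if int(prof.counts[30]) == 2 and int(prof.counts.min()) == 2:
            out["two_mismatch"] = (frag, GeneRecord("ot_a", ot_a, Role.OFFTARGET))
            break

    # (b) clean instance
    frag, ot = _clean_pair()
    out["clean"] = (frag, GeneRecord("ot_b", ot, Role.OFFTARGET))

    # (c) >= 3 Hamming everywhere but one miRNA-like site with a 2-nt loop
    while True:
        frag, ot = _clean_pair()
        k = 30
        guide = list(_rc(frag[k : k + w]))
        guide[5] = _BASES[(int(_BASES.tolist().index(guide[5])) + 1) % 4]  # pos 6
        loop = _rand(2)
        rc_site = "".join(guide[:16]) + loop + "".join(guide[16:])
        site = _rc(rc_site)  # 23 nt on the off-target sense strand
        ot_c = ot[:200] + site + ot[200 + len(site) :]
        prof = min_distance_scan(frag, ot_c, cfg.both_strands, window_len=w)
        if int(prof.counts.min()) < cfg.min_mismatch:
            continue
        from .mirna import screen_fragment_windows as _screen

        hits = _screen(
            frag, ot_c, np.arange(len(frag) - w + 1),
            window_len=w, both_strands=cfg.both_strands,
        )
        if hits and k in hits:
            out["mirna_loop"] = (frag, GeneRecord("ot_c", ot_c, Role.OFFTARGET))
            break
    return out


def make_min_run_family(
    seed: int = 0,
    run_windows: int = 49,
    constraints: DesignConstraints | None = None,
) -> tuple[GeneFamily, str, int]:
    """A two-gene family whose longest run of valid windows supports a
    fragment of exactly ``run_windows + window_len - 1`` nt (69 by
    default): the off-target equals the source except for substitutions
    every 7 nt across one stretch, so windows inside the stretch see
    exactly 3 mismatches and windows straddling its edges see at most 2.
    Built for the minimum-fragment-length rule; the miRNA filter is not
    part of this construction (screen with apply_mirna_rules=False).

    Returns ``(family, source_id, run_start)``; the source is the
    intended target, the mutated copy the off-target.
    """
    cfg = constraints or DesignConstraints(apply_mirna_rules=False)
    w = cfg.window_len
    if (run_windows + 14) % 7 != 0:
        raise ValueError("run_windows must be 7*k - 14 for integer k >= 3")
    n_mut = (run_windows + 14) // 7
    rng = np.random.default_rng(seed)
    s = 100
    grid_start = s + w - 15  # first mutated position; run then starts at s
    from .designer import build_validity_mask

    while True:
        src = _decode(rng.integers(0, 4, 300, dtype=np.int8))
        ot = list(src)
        for k in range(n_mut):
            p = grid_start + 7 * k
            ot[p] = _BASES[(int(_BASES.tolist().index(ot[p])) + 1 + int(rng.integers(0, 3))) % 4]
        family = GeneFamily(
            [
                GeneRecord("src", src, Role.INTENDED),
                GeneRecord("ot", "".join(ot), Role.OFFTARGET),
            ]
        )
        mask = build_validity_mask(family["src"], [family["ot"]], cfg)
        expect = np.zeros(mask.valid.size, dtype=bool)
        expect[s : s + run_windows] = True
        if np.array_equal(mask.valid, expect):
            return family, "src", s
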