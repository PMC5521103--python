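import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vigsdesign import (
    DesignConstraints,
    FamilySpec,
    GeneFamily,
    GeneRecord,
    PlantSpec,
    Role,
    Verdict,
    build_chimera,
    evaluate_fragment,
    generate_family,
    partition_subgroups,
    plant_region,
    revcomp,
    search_fragments,
    wallace_tm,
)

import oracles


def _passing_pair(seed):
    """Two fragments + one off-target, all random, every fragment PASS."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n):
        return "".join(bases[rng.integers(0, 4, n)])

    while True:
        a, b, ot = rand(80), rand(80), rand(300)
        # hosts stay neutral so each fragment's efficacy is judged against
        # its own source, not the other fragment's gene
        ga = GeneRecord("ga", a, Role.NEUTRAL)
        gb = GeneRecord("gb", b, Role.NEUTRAL)
        rec = GeneRecord("ot", ot, Role.OFFTARGET)
        fam = GeneFamily([ga, gb, rec])
        cfg = DesignConstraints()
        ca = evaluate_fragment(ga, 0, 80, fam, cfg)
        cb = evaluate_fragment(gb, 0, 80, fam, cfg)
        if ca.verdict is Verdict.PASS and cb.verdict is Verdict.PASS:
            return fam, ca, cb, rng


class TestPartition:
    def test_identical_members_form_one_subgroup(self):
        fam = GeneFamily([GeneRecord(f"g{i}", "ACGT" * 20) for i in range(4)])
        sgs = partition_subgroups(fam, 90.0)
        assert len(sgs) == 1
        assert set(sgs[0].member_ids) == set(fam.ids)

    def test_threshold_100_on_distinct_sequences_gives_singletons(self, rng, dna):
        fam = GeneFamily([GeneRecord(f"g{i}", dna(rng, 80)) for i in range(4)])
        sgs = partition_subgroups(fam, 100.0)
        assert len(sgs) == 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_planted_subgroups_exactly(self, seed):
        fam, labels = generate_family(FamilySpec(seed=seed))
        sgs = partition_subgroups(fam, 90.0)
        pred = {}
        for k, sg in enumerate(sgs):
            for mid in sg.member_ids:
                pred[mid] = k
        truth = [labels[m] for m in fam.ids]
        guess = [pred[m] for m in fam.ids]
        assert adjusted_rand_score(truth, guess) == pytest.approx(1.0)

    def test_representative_is_a_member(self):
        fam, _ = generate_family(FamilySpec(seed=4))
        for sg in partition_subgroups(fam, 90.0):
            assert sg.representative_id in sg.member_ids

    def test_partitions_refine_as_threshold_rises(self):
        fam, _ = generate_family(FamilySpec(seed=6))
        coarse = partition_subgroups(fam, 80.0)
        fine = partition_subgroups(fam, 95.0)
        coarse_sets = [set(s.member_ids) for s in coarse]
        for s in fine:
            assert any(set(s.member_ids) <= c for c in coarse_sets)

    def test_bad_threshold_rejected(self):
        fam = GeneFamily([GeneRecord("a", "ACGT" * 10)])
        with pytest.raises(ValueError):
            partition_subgroups(fam, 0.0)


class TestChimera:
    def test_single_fragment_construct_equals_fragment(self):
        fam, ca, _, _ = _passing_pair(1)
        construct = build_chimera([ca], fam)
        assert construct.insert_seq == ca.seq
        assert construct.junctions == []
        assert construct.verdict is Verdict.PASS

    def test_failing_fragment_rejected_before_assembly(self, rng, dna):
        gene = GeneRecord("g", dna(rng, 80), Role.INTENDED)
        ot = GeneRecord("ot", gene.seq, Role.OFFTARGET)  # identical -> fail
        fam = GeneFamily([gene, ot])
        bad = evaluate_fragment(gene, 0, 80, fam)
        assert bad.verdict is Verdict.FAIL
        with pytest.raises(ValueError, match="verdict"):
            build_chimera([bad], fam)

    def test_planted_junction_site_fails_and_names_the_junction(self):
        """A 21-mer minted across the junction, planted into an off-target
        at Hamming distance 2, must flip the construct verdict."""
        for seed in range(50):
            fam, ca, cb, rng = _passing_pair(100 + seed)
            junction_kmer = (ca.seq + cb.seq)[70:91]  # spans the boundary
            mutated = list(junction_kmer)
            for p in rng.choice(21, 2, replace=False):
                mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
            ot = fam["ot"].seq
            ot2 = ot[:150] + "".join(mutated) + ot[171:]
            fam2 = GeneFamily(
                [fam["ga"], fam["gb"], GeneRecord("ot", ot2, Role.OFFTARGET)]
            )
            ca2 = evaluate_fragment(fam2["ga"], 0, 80, fam2)
            cb2 = evaluate_fragment(fam2["gb"], 0, 80, fam2)
            if not (ca2.verdict is Verdict.PASS and cb2.verdict is Verdict.PASS):
                continue  # planting collided with a fragment window; next seed
            construct = build_chimera([ca2, cb2], fam2)
            assert construct.verdict is Verdict.FAIL
            assert any("junction window" in v for j in construct.junctions for v in j.violations)
            assert not oracles.fragment_clean(construct.insert_seq, [ot2])
            return
        pytest.fail("no usable constructed instance in 50 seeds")

    @pytest.mark.parametrize("trial", range(5))
    def test_verdict_matches_brute_force_full_insert_rescreen(self, trial):
        fam, ca, cb, rng = _passing_pair(200 + trial)
        if trial % 2:  # sometimes plant a near-match at the junction
            jk = list((ca.seq + cb.seq)[72:93])
            p = int(rng.integers(0, 21))
            jk[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[jk[p]]
            ot2 = fam["ot"].seq[:100] + "".join(jk) + fam["ot"].seq[121:]
            fam = GeneFamily(
                [fam["ga"], fam["gb"], GeneRecord("ot", ot2, Role.OFFTARGET)]
            )
            ca = evaluate_fragment(fam["ga"], 0, 80, fam)
            cb = evaluate_fragment(fam["gb"], 0, 80, fam)
            if not (ca.verdict is Verdict.PASS and cb.verdict is Verdict.PASS):
                pytest.skip("planted site collided with a fragment window")
        construct = build_chimera([ca, cb], fam)
        brute = oracles.fragment_clean(construct.insert_seq, [fam["ot"].seq])
        assert (construct.verdict is Verdict.PASS) == brute

    def test_insert_length_bounds_warning(self):
        fam, ca, cb, _ = _passing_pair(3)
        construct = build_chimera([ca, cb], fam)  # 160 nt < 200
        assert any("insert length" in w for w in construct.warnings)

    def test_six_subgroup_representative_fragments_assemble_in_bounds(self):
        """End-to-end: plant one qualifying region per subgroup
        representative (shared with its co-members), search it, and link
        the six fragments into one insert, as the multi-gene silencing
        design prescribes."""
        fam, labels = generate_family(FamilySpec(seed=8))
        sizes = {}
        for mid, lab in labels.items():
            sizes.setdefault(lab, []).append(mid)
        planted = fam
        spans = {}
        for k, (lab, members) in enumerate(sorted(sizes.items())):
            host = members[0]
            start = 60 + 40 * k
            planted, span = plant_region(
                planted,
                PlantSpec(
                    host,
                    start,
                    80,
                    guarantee="exact_shared_with" if len(members) > 1 else "min_mismatch_ge_3",
                    shared_with=tuple(members[1:]),
                ),
                seed=900 + k,
            )
            spans[host] = span
        candidates = []
        for host, (lo, hi) in spans.items():
            group = {m for m, lab in labels.items() if lab == labels[host]}
            roles = {
                m: ("intended" if m in group else "offtarget") for m in planted.ids
            }
            fam_r = planted.with_roles(roles)
            res = search_fragments(fam_r[host], fam_r)
            assert len(res) >= 1
            candidates.append(res[0])
        all_intended = planted.with_roles({m: "intended" for m in planted.ids})
        construct = build_chimera(candidates, all_intended)
        assert construct.verdict is Verdict.PASS
        lo, hi = DesignConstraints().insert_len_bounds
        assert lo <= construct.total_len <= hi
        assert len(construct.junctions) == 5
        assert len(construct.primers) == 2 + 2 * 5


class TestPrimers:
    def test_bridge_is_flanking_forty_mer(self):
        fam, ca, cb, _ = _passing_pair(5)
        construct = build_chimera([ca, cb], fam)
        bridge = next(p for p in construct.primers if p.name == "bridge_1_fwd")
        assert bridge.seq == ca.seq[-20:] + cb.seq[:20]
        rev = next(p for p in construct.primers if p.name == "bridge_1_rev")
        assert revcomp(rev.seq) == bridge.seq

    def test_wallace_rule_hand_example(self):
        assert wallace_tm("AAAAAAAAAAGGGGGGGGGG") == 60.0

    def test_terminal_primers_come_from_insert_ends(self):
        fam, ca, cb, _ = _passing_pair(6)
        construct = build_chimera([ca, cb], fam)
        fwd = next(p for p in construct.primers if p.name == "terminal_fwd")
        rev = next(p for p in construct.primers if p.name == "terminal_rev")
        assert fwd.seq == construct.insert_seq[:20]
        assert rev.seq == revcomp(construct.insert_seq[-20:])

    def test_short_fragment_rejected(self):
        from vigsdesign.builder import design_overlap_primers

        fam, ca, _, _ = _passing_pair(7)
        construct = build_chimera([ca], fam)
        with pytest.raises(ValueError, match="primer_half_len"):
            design_overlap_primers(construct, primer_half_len=100)
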