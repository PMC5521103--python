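import numpy as np
import pytest

from vigsdesign import (
    min_distance_scan,
    mismatch_site_table,
    profile_to_tsv,
    render_alignment_report,
    revcomp,
    tabulate_mismatch_sites,
    window_mismatches_aligned,
)

import oracles

SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate(seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = SUB[out[p]]
    return "".join(out)


class TestAlignedMode:
    def test_identical_pair_all_zero(self, rng, dna):
        seq = dna(rng, 50)
        prof = window_mismatches_aligned(seq, seq)
        assert prof.n_windows == 30
        assert (prof.counts == 0).all()

    def test_two_substitutions_match_window_enumeration(self, rng, dna):
        # 25-nt pair differing at positions 5 and 12: every window of the
        # 5 possible ones covers both -> all counts 2 (brute enumeration)
        a = dna(rng, 25)
        b = mutate(a, [5, 12])
        prof = window_mismatches_aligned(a, b)
        expected = [
            sum(1 for p in (5, 12) if i <= p <= i + 20) for i in range(5)
        ]
        assert prof.counts.tolist() == expected == [2] * 5

    def test_scattered_substitutions_match_enumeration(self, rng, dna):
        a = dna(rng, 60)
        muts = [3, 25, 44, 58]
        b = mutate(a, muts)
        prof = window_mismatches_aligned(a, b)
        expected = [
            sum(1 for p in muts if i <= p <= i + 20) for i in range(40)
        ]
        assert prof.counts.tolist() == expected

    def test_deletion_gap_column_counts_for_covering_windows(self):
        # 30-nt fragment; comparator lacks the fragment's position 15.
        # The fragment base at 15 becomes a gap column: +1 for every
        # window covering position 15 (starts 0..9 here), pinned by
        # making position 15 unique in its neighborhood.
        frag = "ACGTACGTACGTAAA" + "G" + "TCCTACGTACGTAC"
        comp = frag[:15] + frag[16:]
        prof = window_mismatches_aligned(frag, comp)
        assert prof.counts.tolist() == [1] * 10

    def test_short_fragment_gives_empty_profile_with_note(self):
        prof = window_mismatches_aligned("ACGT", "ACGT")
        assert prof.n_windows == 0
        assert "shorter than window" in prof.note


class TestScanMode:
    def test_verbatim_containment_gives_zero(self, rng, dna):
        frag = dna(rng, 40)
        tran = dna(rng, 100) + frag + dna(rng, 50)
        prof = min_distance_scan(frag, tran)
        assert (prof.counts == 0).all()

    def test_revcomp_transcript_both_strands(self, rng, dna):
        frag = dna(rng, 50)
        tran = revcomp(frag)
        both = min_distance_scan(frag, tran, both_strands=True)
        assert (both.counts == 0).all()
        sense = min_distance_scan(frag, tran, both_strands=False)
        assert sense.counts.tolist() == oracles.scan_counts_pure(frag, tran, both=False)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pure_python_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        bases = np.array(list("ACGT"))
        frag = "".join(bases[rng.integers(0, 4, int(rng.integers(70, 121)))])
        tran = "".join(bases[rng.integers(0, 4, int(rng.integers(21, 301)))])
        prof = min_distance_scan(frag, tran, both_strands=True)
        assert prof.counts.tolist() == oracles.scan_counts_pure(frag, tran, both=True)

    def test_transcript_shorter_than_window_warns_and_saturates(self, rng, dna):
        frag = dna(rng, 30)
        with pytest.warns(UserWarning, match="shorter than"):
            prof = min_distance_scan(frag, "ACGT")
        assert (prof.counts == 21).all()

    def test_scan_never_exceeds_aligned_counts(self, rng, dna):
        # scan minimizes over all placements, aligned mode fixes one
        for _ in range(5):
            a = dna(rng, 80)
            b = mutate(a, rng.choice(80, size=6, replace=False))
            aligned = window_mismatches_aligned(a, b)
            scan = min_distance_scan(a, b)
            assert (scan.counts <= aligned.counts).all()

    def test_strand_symmetry(self, rng, dna):
        frag, tran = dna(rng, 60), dna(rng, 150)
        both = min_distance_scan(frag, tran, both_strands=True).counts
        sense = min_distance_scan(frag, tran, both_strands=False).counts
        anti = min_distance_scan(frag, revcomp(tran), both_strands=False).counts
        assert (both == np.minimum(sense, anti)).all()

    def test_extending_transcript_never_increases_counts(self, rng, dna):
        frag, tran = dna(rng, 60), dna(rng, 100)
        short = min_distance_scan(frag, tran).counts
        long = min_distance_scan(frag, tran + dna(rng, 80)).counts
        assert (long <= short).all()


class TestSiteTabulation:
    def test_identical_pair_has_no_sites(self, rng, dna):
        seq = dna(rng, 60)
        prof = window_mismatches_aligned(seq, seq)
        assert tabulate_mismatch_sites(prof, 1) == 0
        assert tabulate_mismatch_sites(prof, 2) == 0

    def test_single_substitution_is_one_site(self, rng, dna):
        a = dna(rng, 60)
        prof = window_mismatches_aligned(a, mutate(a, [30]))
        assert tabulate_mismatch_sites(prof, 1) == 1
        assert tabulate_mismatch_sites(prof, 2) == 0

    def test_two_distant_substitutions_are_two_sites(self, rng, dna):
        a = dna(rng, 80)
        prof = window_mismatches_aligned(a, mutate(a, [20, 60]))
        assert tabulate_mismatch_sites(prof, 1) == 2

    def test_invalid_k_rejected(self, rng, dna):
        a = dna(rng, 40)
        prof = window_mismatches_aligned(a, a)
        with pytest.raises(ValueError):
            tabulate_mismatch_sites(prof, -1)
        with pytest.raises(ValueError):
            tabulate_mismatch_sites(prof, 22)

    def test_scan_profile_rejected(self, rng, dna):
        prof = min_distance_scan(dna(rng, 40), dna(rng, 60))
        with pytest.raises(ValueError, match="aligned"):
            tabulate_mismatch_sites(prof, 1)

    def test_site_table_shape(self, rng, dna):
        a = dna(rng, 60)
        table = mismatch_site_table(
            a, {"c1": mutate(a, [10]), "c2": mutate(a, [10, 40])}
        )
        assert list(table.columns) == ["k=1", "k=2"]
        assert table.loc["c1", "k=1"] == 1
        assert table.loc["c2", "k=1"] == 2


class TestExports:
    def test_tsv_columns_are_1based(self, rng, dna):
        a = dna(rng, 30)
        df = profile_to_tsv(min_distance_scan(a, dna(rng, 60)))
        assert df["window_start_1based"].iloc[0] == 1
        assert len(df) == 10

    def test_alignment_report_mentions_low_mismatch_stretches(self, rng, dna):
        a = dna(rng, 60)
        report = render_alignment_report(a, mutate(a, [30]), highlight_max=2)
        assert "silencing-competent" in report
        assert "1-" in report  # at least one annotated stretch
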