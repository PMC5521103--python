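# Methods

This note records the model behind `vigsdesign`, the conventions the
implementation had to fix where the underlying method leaves choices
open, and what the synthetic-data experiments do and do not demonstrate.

## The specificity model

Silencing specificity is evaluated at the level of 21-nt windows, the
lower end of the 21–24-nt siRNA size range and therefore the most
conservative choice (a 21-nt window that qualifies also qualifies as part
of any longer siRNA). Two screens are applied to every window of a
candidate fragment, against every off-target:

1. **Hamming screen (primary).** The window must have at least
   `min_mismatch = 3` mismatches to *every* k-mer of the off-target, on
   both strands. The threshold encodes the empirical finding that
   windows with one or two mismatches still silence the off-target,
   while three or more prevent silencing. The scan minimizes over all
   off-target registers rather than only the aligned one, because siRNAs
   pair with any complementary stretch of the message, not with the
   position an alignment happens to put opposite the fragment. An
   alignment-anchored mode exists alongside for reporting (underlined
   21-bp stretches, per-comparator mismatch-site tables), with gap
   columns counted as mismatches — the conservative choice for
   silencing risk.

2. **miRNA-like-trigger screen (secondary).** An siRNA with one or two
   mismatches can still down-regulate a transcript through miRNA-like
   recognition. A window is rejected when any of its siRNAs (antisense
   guide; sense polarity too when both strands are screened, since VIGS
   produces dsRNA) has a *functional* site anywhere on an off-target.
   Functionality follows the published artificial-miRNA rules: guide
   positions 2–12 tolerate at most one mismatch; the cleavage site
   opposite positions 10–11 must pair; the 3′ region (positions 13–21)
   tolerates a mismatch loop of at most two target nucleotides; a
   perfectly paired, loop-free 3′ region compensates up to two 5′
   mismatches; guide position 1 is outside the pairing budget.

### Conventions fixed by this package

* **Total-mismatch cap.** The rule set is additionally closed with a cap
  of two substitution mismatches in total
  (`MirnaRuleConfig.max_total_mismatch = 2`). Without it, one seed
  mismatch plus two 3′ mismatches (three substitutions in total) would
  count as functional, making the secondary filter reject windows that
  the ≥ 3-mismatch rule was shown to protect; the filter is motivated by
  siRNAs *within* two mismatches of an off-target, and the cap keeps the
  two screens complementary: on loop-free sites the miRNA filter never
  fires where the Hamming screen already guarantees three mismatches,
  so everything it adds comes from loop-containing sites.
* **Cleavage stringency.** Positions 10–11 are required to pair
  strictly rather than merely being included in the 5′ budget; this is
  the stricter of the two readings and is configurable
  (`cleavage_positions`).
* **Loop geometry.** Loops are modeled as 1–2 unpaired target-side
  nucleotides inserted between two guide positions of the 3′ region;
  guide-side bulges are out of scope. Sites longer than the tolerated
  loop are evaluated and reported non-functional (a 3-nt loop is a
  meaningful negative verdict, not an input error).
* **G:U wobble** counts as a mismatch by default; a config flag can
  relax it.
* **Site merging.** For the tabulated "number of sites with exactly k
  mismatches per 21-bp stretch", maximal runs of equal-count windows
  collapse into one site while they share at least one mismatch column,
  walked greedily left to right. This mimics counting discrete
  underlined stretches in an alignment figure; the raw per-window counts
  are always retained so no user is bound to the merging convention.

## Fragment search

A validity mask marks every window start of the source gene that passes
both screens against all off-targets (the cheap Hamming screen first;
the miRNA scan only for surviving windows, which it can only remove).
Maximal runs of valid windows yield maximal fragments: a run of R
consecutive starts supports up to R + 20 nt, truncated to
`max_fragment_len`. Fragments shorter than `min_fragment_len`
(default 70 nt — the shortest length shown to silence efficiently) are
reported as diagnostics naming the constraint that ended the run.

Efficacy is judged per intended target as "at least one window matching
with zero mismatches" (coverage = fraction of zero-mismatch windows).
The method's designs rely on near-perfect identity between the fragment
and its co-targets, but no quantitative efficacy threshold is
established; the ≥ 1 exact window default is a declared convention. A
shared identical stretch of 11–20 nt triggers a warning either way,
since stretches that short have been associated with ~15% knockdown.

Ranking is by (1) specificity margin — the minimum over off-targets of
the per-window minimum mismatch count — descending, (2) mean intended
coverage descending, (3) leftmost start (an arbitrary but deterministic
tie-break).

## Construct assembly

Subgroups are obtained by single-linkage clustering on global pairwise
percent identity (Needleman–Wunsch, match +1 / mismatch −1 / gap open −2
/ gap extend −1; on the near-identical, equal-length inputs this method
targets the optimal alignment is effectively ungapped, so identity
reduces to Hamming identity). Clustering operationalizes the subgroup
notion a phylogenetic tree would provide, with a testable ground truth;
tree building itself is out of scope. The representative of a subgroup
is the member with the highest mean identity to its co-members.

Concatenating fragments mints `window_len − 1` novel windows per
junction. These are screened exactly like fragment windows (Hamming and
miRNA screens against all off-targets); the construct verdict is PASS
iff all fragments and all junction windows pass. Junction screening is
not part of the original bench protocol but is logically required; it
can be disabled for strict emulation. No linker is inserted between
fragments by default (direct abutment); a linker string is accepted and
screened as part of the junction region. The whole-insert length is
checked against the TRV insert bounds (200–1500 bp) as a warning, not an
error. Overlap-extension primers are built per junction as the last
`h = 20` nt of the upstream fragment plus the first `h` of the
downstream one (plus reverse complements and terminal primers), with
melting temperatures by the Wallace rule 2(A+T) + 4(G+C) — chosen for
exact testability; nearest-neighbor thermodynamics is a non-goal.

## Synthetic families

The generator draws a uniform-random ancestor (default 450 nt), derives
subgroup ancestors by i.i.d. substitution at `between_divergence`
(default 0.15) and members at `within_divergence` (default 0.02), with
substitutions uniform over the three alternative bases. Defaults mimic a
12-member family in six subgroups of sizes 3, 3, 2, 2, 1, 1. Under this
model two sequences derived at rate p from a common ancestor match per
site with probability (1 − p)² + p²/3, which the calibration check
verifies to within 3 standard errors over 50 seeds. Indels are off by
default (the regions of interest align without gaps) and exercised only
in dedicated gap-handling tests. Codon structure, GC bias, selection and
branch-length realism are not modeled — so passing tests demonstrate the
correctness of the screens and the search on families with this
divergence structure, not performance on any particular real gene
family, whose homology is block-wise rather than i.i.d.

`plant_region` rewrites one region of a host member by rejection
sampling until the region passes the *full* specificity screen against
every other member (not only the Hamming part: when the constraints
enable the miRNA filter the planted region must clear it too, otherwise
a chance miRNA-like site can split the planted run and the region would
not actually qualify). The `exact_shared_with` variant copies the
identical region into listed co-members, giving efficacy by
construction; those members are excluded from the specificity guarantee.

Two engineered instances back the rule-discrimination and
minimum-length checks. The discrimination triple plants (a) a
2-mismatch window, (b) nothing (clean random pair), (c) a site with one
seed mismatch plus a 2-nt 3′ loop behind a ≥ 3-Hamming margin. The
minimum-length family mutates an off-target copy of the source every
7 nt across one stretch, so interior windows see exactly three
mismatches and edge-straddling windows at most two, yielding a valid run
of exactly 49 windows = 69 nt; this instance is screened with the miRNA
filter off, because windows whose edge mismatch falls on guide
position 1 (ignored by the pairing rules) reduce to two counted
mismatches and would deterministically punch holes in the run —
the check isolates the length rule.

## Problem sizes and numerics

The property checks run at the scale the method is used at: 200 random
fragment/transcript pairs for exact oracle equivalence of the scan
engine; all ~930 mismatch/loop placements for the duplex rules; 100
seeds of planted-region recovery on the default 12-member family with
brute-force re-verification of every returned candidate; 20 seeds of
subgroup recovery (adjusted Rand index 1.0 required); 50 random
assemblies for junction-screen soundness; 50 seeds for generator
calibration. The oracles are deliberately naive: per-window all-pairs
Hamming comparison, and plain-loop enumeration of every admissible
duplex alignment (with an exact seed-region impossibility filter, since
the 5′ region pairs with the same target columns for every loop
placement).

Degenerate inputs are handled explicitly: fragments shorter than the
window give an empty profile with a note; transcripts shorter than the
window saturate scan counts at `window_len` with a warning; a source
shorter than `min_fragment_len` is an error rather than a silent empty
result; an empty off-target set makes specificity vacuously true with a
notice.

## Known limitations

* Specificity is sequence-only: no thermodynamic siRNA scoring, no
  target-site accessibility, no expression data.
* Efficacy is a declared convention (≥ 1 exact window), not a fitted
  model of silencing strength.
* The miRNA rule set is a discrete rule table; quantitative deviations
  (position-specific weights, wobble energetics) are out of scope.
* DNA alphabet is strict ACGT; ambiguity codes are rejected rather than
  expanded, because exact window mismatch counts would otherwise be
  ill-defined.
* Genome-wide screening is supported only in the sense that any FASTA
  transcript can be supplied as an off-target; no indexing is done, so
  transcriptome-scale scans are linear per transcript.
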