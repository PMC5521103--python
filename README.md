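# vigsdesign

Design of short, member-specific trigger fragments for virus-induced gene
silencing (VIGS) in highly homologous gene families, and of chimeric
multi-gene silencing constructs.

## The problem

VIGS knocks a plant gene down by carrying a fragment of it in a viral
vector (typically *Tobacco rattle virus*, TRV): the infection produces
double-stranded RNA that is diced into 21–24-nt siRNAs, which degrade any
transcript they match. In a family of near-identical genes this is a
trap: an siRNA that matches a *different* family member closely enough
silences it too. The widely used safeguard — avoid any 21-bp stretch of
perfect identity with other genes — is not sufficient: windows with only
one or even two mismatches to another member still silence it. Silencing
is only prevented when **every 21-bp window of the fragment carries at
least three mismatches to every off-target**. As a secondary hazard, an
siRNA with one or two mismatches can still act like a plant miRNA when
its pairing satisfies the miRNA target-recognition rules (at most one
mismatch at guide positions 2–12 including a paired cleavage site at
10–11; a 3′ mismatch loop of at most 2 nt; a perfect 3′ end compensating
up to two 5′ mismatches). On the efficacy side, fragments as short as
~70 bp silence efficiently, which matters because qualifying regions in a
tight family are short.

`vigsdesign` implements this selection method end to end:

* **window engine** — for every 21-bp window of a fragment, the minimum
  Hamming distance to *any* k-mer of an off-target transcript (both
  strands), plus alignment-anchored window profiles and mismatch-site
  tables for reporting;
* **miRNA rules** — exact scoring of siRNA/target duplexes under the
  pairing rules above, and exhaustive site scans with 0–2-nt target
  loops;
* **fragment search** — a per-window validity mask over the source gene
  (≥ 3 mismatches per window against every off-target, no miRNA-like
  site), maximal qualifying fragments within length bounds (default
  70–400 nt), ranked by specificity margin;
* **construct builder** — single-linkage subgroup clustering on percent
  identity, concatenation of subgroup-representative fragments into one
  chimeric insert (TRV bounds 200–1500 bp), re-screening of every novel
  junction-spanning window, and overlap-extension PCR primers
  (Wallace-rule Tm);
* **synthetic families** — a deterministic generator of homologous
  families with ground-truth subgroups and plantable guaranteed-valid
  regions, so the whole pipeline is testable without any downloads.

## Worked example

```bash
python examples/01_design_fragment.py
```

```
planted qualifying region in m01 at 201-280 (1-based)
1 qualifying fragment(s):
  m01:184-297  len=114 nt  specificity margin=3 mismatches/window  coverage(m01)=1.00
```

A 12-member synthetic family is generated, an 80-nt region guaranteed to
satisfy all constraints is planted into member m01, and the search
returns one fragment containing it. The *specificity margin* is the
smallest mismatch count any of its 21-bp windows has to any off-target
k-mer — 3 or more means no off-target silencing is expected — and
*coverage* 1.00 means every window matches the intended gene exactly, so
silencing of m01 itself is efficient. The other examples walk through
window reports (`02`), the miRNA duplex rules (`03`), subgroup clustering
(`04`) and chimeric-insert assembly with junction screening and primers
(`05`).

The same operations are available from a shell:

```bash
vigsdesign simulate --seed 11 --plant-host m01 --fasta-out family.fasta
vigsdesign design family.fasta --intended m01
vigsdesign cluster family.fasta --threshold 90
```

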