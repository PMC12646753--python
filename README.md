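# coievol

Comparative analysis of mitochondrial **COI barcode** evolution in
**haplodiploid (HD)** versus **diplodiploid (DD)** insect lineages.

Haplodiploidy — males haploid or functionally haploid — has evolved
repeatedly in insects, and HD lineages show conspicuously accelerated
mitogenome evolution.  `coievol` packages the comparative analysis that
measures this acceleration in the ~658 bp COI barcode region (~220 codons,
translation table 5):

- **QC & stratified sampling** of barcode records: the 643–661 bp amplicon
  window, one sequence per BIN (the species proxy), reading-frame/stop-codon
  screening for NUMT suspects, per-family and per-subfamily sampling caps,
  and exclusion of families with fewer than three BINs.
- **Family consensus** sequences by the most-common-base rule, translated
  under the invertebrate mitochondrial code, with amino-acid substitution
  counts against dipluran/proturan-style outgroups.
- **Divergence metrics**: amino-acid *p*-distance, Poisson distance
  −ln(1 − *p*), quartile classification of substitution counts, and the
  outgroup-concordance *r*².
- **Ka/Ks (ω)** by Nei–Gojobori-style pathway counting under table 5 with
  Jukes–Cantor correction: per-pair, per-family medians over all BIN pairs,
  and a pooled branch-class contrast ω_HD / ω_DD.
- **Indel events**: 1–2-codon amino-acid indels called against the overall
  insect consensus, classified as insertions/deletions, and reduced to
  parsimony-minimal event counts on the family tree (absence ancestral).
- **Trait ANOVA**: majority-rule family assignment of reproduction (HD/DD),
  lifestyle (free-living/parasite) and locomotion (winged/flightless
  females), then a three-factor type-II ANOVA of family median ω.
- A **synthetic cohort generator** that produces in-frame COI-like
  sequences under a codon model with branch-class-specific ω, planted
  indels, taxonomy/trait sidecars and a labelled family tree — so the whole
  pipeline is testable end to end without any sequence download.

The core quantity is ω = Ka/Ks, estimated by counting: per codon,
synonymous site fractions come from enumerating the nine single-nucleotide
mutants (stop mutants excluded from the opportunity); differences between
codons are averaged over mutational pathways; then

    pS = ΣSd / ΣS_sites,   Ks = −(3/4)·ln(1 − (4/3)·pS)

(and likewise Ka), with ω = Ka/Ks.  The class contrast pools raw counts
over all within-family pairs of each class before correcting.

## Worked example

`examples/02_kaks_contrast.py` simulates 60 families (half HD at
generating ω = 0.0875, half DD at ω = 0.0252), runs the counting estimator
over every within-family BIN pair and pools per class:

```
$ python examples/02_kaks_contrast.py
pooled omega HD: 0.0949 (generating 0.0875, 300 pairs)
pooled omega DD: 0.0253 (generating 0.0252, 300 pairs)
HD:DD ratio    : 3.75 (generating 3.47)
```

Both class estimates sit near their generating values (ω ≪ 1: strong
purifying selection on COI) and the ratio recovers the ~3.5-fold weaker
constraint in HD lineages.  The other examples cover cohort generation,
indel calling with exact truth recovery, the trait ANOVA, and the full
pipeline (`coievol simulate | run | report` from the shell does the same).

## Layout

```
src/coievol/     qc, consensus, divergence, kaks, indels, anova,
                 simulate, pipeline, cli
examples/        one short narrative script per capability
tests/           pytest suite (unit, property and recovery tests)
docs/methods.md  models, parameter choices, numerical conventions, limits
```
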