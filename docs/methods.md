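# Methods

## The question and the measurement

Haplodiploid (HD) insect lineages accumulate mitochondrial amino-acid
changes faster than diplodiploid (DD) ones.  The measurable signature in
the COI barcode is threefold: more amino-acid substitutions relative to a
deep outgroup, a higher ω = Ka/Ks among closely related species (BINs) of
the same family, and a strong excess of 1–2-codon indels.  `coievol`
implements the counting-based version of this analysis plus a simulator
that generates cohorts with exactly the structure the analysis assumes, so
every stage can be validated against planted truth.

## Ka/Ks estimator

We use Nei–Gojobori-style counting under the invertebrate mitochondrial
code (table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp, stops TAA/TAG only):

* **Sites.**  For each codon position, the synonymous fraction is taken
  over the non-stop single-nucleotide mutants, so each position contributes
  one site and S + N = 3 per codon.  Codons containing gaps or N in either
  member of a pair are skipped pairwise.
* **Differences.**  Codon pairs differing at 2–3 positions average Sd/Nd
  over all orderings of single steps; orderings passing through a stop are
  excluded (with an include-all fallback that cannot trigger between sense
  codons under table 5 but guards other codes).
* **Correction.**  Jukes–Cantor on the proportions; arguments ≥ 3/4 mark a
  pair unusable, as does Ks = 0 (ω undefined).
* **Family summaries** take the median ω over all C(n,2) usable BIN pairs;
  unusable pairs are tallied by reason, and a family with no usable pair is
  flagged and excluded downstream.
* **The class contrast** pools raw counts (ΣSd, ΣNd, Σsites) over all
  within-family pairs of each class before correcting, then takes
  ω_HD / ω_DD.  Count pooling weights every codon site equally and avoids
  the small-Ks blow-ups a mean of per-pair ratios would suffer; the
  mean-of-family-medians alternative is available from the per-family
  table for sensitivity checks.

The estimator is deliberately the transparent counting one rather than a
likelihood method, so it can be verified to 1e-12 against an enumeration
oracle (see `tests/test_kaks.py`).  Absolute values are therefore not
comparable to branch-site likelihood estimates; the HD:DD contrast is the
reproducible quantity.

## Simulator

* **Tree.**  A rooted ultrametric coalescent-style topology over families;
  the HD families (round(hd_fraction·n)) form one clade, mirroring the
  phylogenetic clustering of haplodiploidy.  Branch lengths are in expected
  *neutral* substitutions per nucleotide site; root-to-tip depth defaults
  to 0.3.
* **Codon process.**  Discrete-event (Gillespie) evolution per branch with
  per-change rate μ·κ^[transition]·ω^[nonsynonymous], μ = 1/(κ+2) so a
  neutral site changes at rate 1; proposals creating stops have rate zero.
  Root codons are uniform over the 62 sense codons, 220 codons long, so the
  canonical barcode frame (660 nt) is reproduced.
* **Generating values.**  ω defaults to 0.0875 (HD) and 0.0252 (DD), the
  class estimates this pipeline is designed to recover.  κ defaults to 1:
  the counting estimator attributes equal opportunity to all mutations, so
  the simulator's default matches the estimator's assumptions and recovery
  checks are interpretable; κ is exposed for sensitivity work (NG86-style
  counting is known to misestimate ω under strong transition bias, which is
  a property of the estimator, not a bug).
* **BIN radiation.**  Within each family, BINs branch off the family
  ancestor as a star with branch length `bin_divergence` (default 0.05
  neutral subs/site, i.e. ~3% realised nucleotide divergence between
  congeneric barcodes).  BIN counts per family follow a skewed
  distribution P(k) ∝ k^(−skew) on [min, max] (default 3–25, skew 1.5);
  the true family-size distribution of barcode corpora is long-tailed but
  unknown, so this is a modelling choice exposed in config.
* **Indels.**  Per family, Poisson(rate) events truncated at 2 (so no
  lineage can leave the 643–661 nt window), length 1 or 2 codons, deletions
  twice as common as insertions by default.  Deletions blank the family's
  codons; insertions add gap columns to every other row and the carrier's
  3′ terminus is trimmed by the inserted length, keeping the ungapped
  length inside the window (trims are recorded separately from events, and
  the indel caller ignores terminal gap runs accordingly — the standard
  treatment of terminal gaps as missing coverage).  Deletion spans and
  insertion anchor points are kept disjoint across families so each planted
  event occupies one contiguous run of alignment columns and truth
  coordinates are exact.
* **Outgroups.**  Two independent long branches (default 0.9) off the root
  under DD-strength selection — dipluran/proturan analogues.
* **Traits.**  Lifestyle and locomotion are assigned per family,
  independent of class by default (p = 0.3 each); a `trait_confounding`
  knob shifts both probabilities upward in HD families to probe the
  ANOVA's factor separation.
* **Determinism.**  All randomness flows from the single config seed
  through named generator streams; identical configs give byte-identical
  files.

What the simulator does *not* emulate: codon usage bias, among-site rate
heterogeneity, within-BIN polymorphism, alignment error, and real BOLD
taxonomy.  Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to those real-data
features.

## Recovery behaviour

On the reference contrast cohort (200 families × 5 BINs × 220 codons) the
pooled class ω recovers its generating value to within a few percent.  On
independent replicates of the cohort geometry the estimator is unbiased;
on full cohorts the estimates fluctuate by roughly ±5–7% between seeds —
more than naive counting error suggests, because all families share one
root and deep branches, so codon-composition drift is correlated across
the whole class.  These fluctuations sit comfortably inside the ±20%
recovery band the tests enforce and are small against the 3.5-fold
contrast being measured.

## QC conventions

* The 643–661 window tests the **ungapped** length: the window concerns the
  amplicon, not alignment columns.
* The reading-frame screen replaces manual verification with an automatic
  rule: best frame = fewest internal stops (ties to the smaller offset),
  zero tolerated internal stops, and any internal gap run not a multiple of
  three flags a frameshift.  N translates to X and never counts as a stop.
* Random selections (one-per-BIN, sampling caps) rank order-independent
  digests of (seed, group, id), so input ordering never changes the
  selection and reruns are exact.  The original corpus draws are not
  reproducible — no seed was published — and no attempt is made to mimic
  them.

## Consensus and indel conventions

* Consensus columns: modal state over {A,C,G,T,−}; N never competes; a gap
  wins only on strict majority over the best residue (so family-fixed
  deletions survive without being inflated); residue ties break by the
  fixed order A > C > G > T.  The original GUI's tie rule is unknowable;
  determinism is the requirement, the order a convention.
* The overall insect consensus is the consensus of family consensuses,
  each family weighted equally.
* Indel event identity is the strict key (start position, length, type) in
  1-based codon columns of the shared alignment; nearby but non-identical
  calls are *not* merged, which may undercount genuinely shared events.
  Minimal event counts fix absence at the tree root (the reference state);
  a gains-only (Dollo) variant is exposed as an option.

## ANOVA

The trait model is a univariate three-factor ANOVA (the response is one
number per family) with the three two-way interactions and no three-way
term.  Factors are coded sum-to-zero, fitted by OLS (statsmodels), and
tested with type-II sums of squares — each term against the model holding
every term not containing it — which is order-invariant under unbalance;
type III is available as a flag.  Exact 50/50 trait splits default to the
ancestral/common level (DD, FL, WW) with a logged tie flag.  Interactions
with empty cells are dropped with a warning.  No phylogenetic correction is
applied in this module: family median ω values are treated as independent,
a documented limitation (the phylogeny enters only the indel event
counting).

## Numerical and scale choices

Quartile thresholds use linear interpolation (type 7), stated in output
metadata since the convention is not standardised; published dataset
cutoffs can be injected as overrides.  The concordance r² is Pearson on
raw counts (rank-based alternative off by default).  Test-suite problem
sizes — 200-family cohorts for recovery, 1000-rep ANOVA calibration at
n = 200, 500-case exhaustive parsimony checks on ≤8-leaf trees — were
chosen so each suite finishes in seconds to a few minutes on one CPU while
keeping Monte-Carlo error well below the tolerances tested.
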