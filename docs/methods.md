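# Methods

This note records the models behind each rhodoquant component, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Alignment engine

All sequence comparison is optimal pairwise dynamic programming
(Needleman–Wunsch global, Smith–Waterman local) with affine gap
penalties, executed by Biopython's C aligner behind the package's own
surface. Conventions:

- **Matrix.** BLOSUM62 over the 20 standard residues; the ambiguity
  character `X` scores 0 against everything (neutral, unlike NCBI's
  penalized X), so ambiguous positions neither help nor hurt.
- **Gaps.** `gap_open = 11`, `gap_extend = 1`, where the *first* column
  of a gap costs 11 and each further column 1 — BLASTP's convention,
  the ecosystem the screening step stands in for. End gaps in global
  mode are penalized the same way.
- **Determinism.** Among co-optimal tracebacks the aligner's first
  enumerated alignment is emitted. This is a fixed, deterministic rule;
  the optimal *score* never depends on it, and every emitted alignment
  satisfies the self-check that rescoring its gapped strings reproduces
  the reported score exactly.
- **Identity.** Percent identity defaults to matches divided by the
  length of the shorter full sequence — the cd-hit convention under
  which the 82% OTU threshold is defined. Matches over alignment
  columns is available where a length-penalizing identity is wanted.
- Input is case-folded; `*` stop characters are stripped with a logged
  warning; any other non-alphabet character is an error naming the
  symbol.

The test suite checks the engine against two independent oracles: a
memoized three-state recursion over the alignment definition, itself
verified against literal enumeration of every alignment at tiny
lengths.

## Reference numbering and residue calls

Positions 97, 101, 105 and 108 refer to a fixed reference coordinate
system. The bundled coordinate template
(`data/pr_reference_synthetic.fasta`) is a **synthetic**
proteorhodopsin-like record, 249 aa, with the canonical residues
planted at those 1-based positions; it defines the numbering and is
fully configurable via `AnnotatedReference` for users who prefer a
natural template. Queries are mapped by a single optimal global
alignment rather than an MSA: for pairwise position lookup the two are
equivalent, and the pairwise route is deterministic and
order-independent.

Calls are pure functions of the mapped residues:

- pump: `functional` iff (97, 101, 108) = (D, T, E); `non_canonical`
  when all three are mapped but differ (e.g. a lysine proton-donor
  position); `undetermined` when any maps to a gap;
- color: L/M → `green`, Q → `blue`, gap → `undetermined`, anything
  else → `unknown` — never coerced to a color, because only those three
  residues have established spectral meaning.

Position profiles (logo-style residue frequencies) are computed over
non-gap residues with gaps counted separately.

## Screening and curation

Two candidate routes share one curation step. The internal route is a
full local alignment against a user-supplied panel (best hit by score,
ties to the lexicographically smaller id; candidates below
`min_bitlike_score = 50` dropped). The external route imports
BLAST/DIAMOND outfmt-6-style tables, keeps rows with E ≤ 10⁻⁷ and the
lowest-E row per query, and takes precedence when supplied — profile
HMM scoring is deliberately out of scope, so real searches should come
in through this importer.

Curation applies exactly two rules: strict length (> 100 aa, so a
100-aa protein fails) and C-helix coverage — the global alignment to
the reference must place non-gap query residues at ≥ 3 of the 4 key
positions. Coverage, not residue identity, is the criterion: a
pump-dead variant (K at 108) is retained and *reported* as
non-canonical downstream. Every rejection is logged with the rule that
failed.

## OTU clustering

Greedy incremental clustering reproduces cd-hit's strategy with exact
DP alignment instead of word-count heuristics, which is affordable at
desk scale and removes heuristic parameters. Visit order is length
descending, ties by id; membership is decided by identity to the
*representative* only; threshold 0.82 with the shorter-sequence
denominator. OTU labels are assigned after clustering, by descending
cluster size then representative id, so `OTU01` is the most populous
cluster. The partition is a pure function of the sequence set — input
order never matters — and equals a brute-force restatement of the rule
in tests.

## Abundance estimator

For sample coverage C(g) = count(g)/length(g) (full gene length,
consistent units across classes):

    f_PR = (1/4) Σ_h  C(PR) / C(h),   h ∈ {recA, rplB, rpoB, EF-Tu}

with PR coverage pooled over all PR genes before each ratio, and each
housekeeping family's coverage summed over all assembled variants of
that family (they represent the same single-copy marker). Pooling PR
coverage first is what makes the statistic "fraction of PR-bearing
cells": averaging per-gene ratios instead would estimate something
else. Fractions above 1 are possible for a ratio of noisy coverages and
are flagged, never clamped — clamping would bias the recovery tests.
A housekeeping family with zero coverage is an error naming the family,
not a silent NaN.

Under the generator's Poisson model the estimator is scale-invariant in
sequencing depth (exactly, under count multiplication) and recovers the
true PR-bearing fraction to within Monte-Carlo error; the suite checks
both.

## Transcription statistic

Relative expression divides a target's transcript coverage by the
*mean* coverage of rplB, rpoB and EF-Tu. recA is excluded from the RNA
normalizer by contract (non-constitutive expression in these waters)
and requesting it raises a configuration error. The statistic is
depth-invariant and self-consistent: the mean relative expression of
the three housekeeping families is identically 1. Transcript coverage
is length-normalized exactly like DNA coverage, for symmetry with the
metagenome statistic. The blue/green transcript partition excludes
unknown-color coverage from its denominator and reports it separately.

## qPCR

Standard curves are ordinary least squares of Cq on log₁₀(copies)
(≥ 3 points, distinct dilutions, negative slope required); efficiency
E = 10^(−1/slope) − 1; slopes outside [−3.9, −3.0] (≈ 80–115%
efficiency) warn rather than fail. Copies are back-calculated from the
*mean* Cq of replicates — standard qPCR practice — with a CV reported
from per-replicate back-calculated copies. The 16S correction assumes
1.9 16S copies and 1 PR copy per genome; per-taxon fractions are
computed independently and are summable into a total. A
below-detection assay is an absent measurement (no Cq), never zero
copies: the package fabricates no limit of detection. No r² acceptance
bound is enforced; r² is reported for the caller to judge.

## Synthetic community generator

The generator emulates the *structure the estimators assume*, not raw
sequencing:

- a community of taxa with relative cell abundances summing to 1, each
  genome carrying exactly one copy of recA, rplB, rpoB and EF-Tu, and
  0 or 1 PR gene of known color; PR-bearing taxa also carry one copy
  each of the retinal-pathway genes blh, crtB and crtY (a PR without
  retinal synthesis capacity would be ecologically incoherent, and the
  transcription module quantifies those genes);
- metagenome counts ~ Poisson(abundance × gene length × depth), so
  expected coverage is abundance × depth; transcript counts carry an
  extra per-gene-class expression multiplier;
- qPCR standards at decade dilutions 10⁸..10² and sample Cq values with
  Gaussian cycle noise around the generating line;
- protein panels derived from the bundled reference by bounded random
  substitutions that never touch the pump triad, with position 105 set
  by the intended color; decoys are rhodopsin-like sequences with the
  C-helix block (reference 91–120) deleted and heavy substitution
  elsewhere, so their optimal global alignment necessarily gaps the key
  region and they fail curation by construction. (A fully random
  full-length protein would usually *pass* a coverage-based rule,
  because a global alignment of similar-length sequences places few
  gaps — hence the deletion-based construction.)

Every generator is a pure function of (specification, seed), and every
simulated sample carries analytic truths computed in closed form from
the specification — recovery tests compare estimates to these, never to
a second simulation.

The packaged study-scale community (`default_community`) fixes ten
taxa, three of them PR-bearing at cell abundances 0.07 + 0.05 (green)
and 0.05 (blue): a PR-bearing fraction of 0.17 with a ~71% green gene
share. Expression multipliers put the blue carrier at 30× and the green
carriers at 5× their housekeeping baseline — blue dominates the
transcript pool (truth 5/7) despite green dominating the DNA — and the
blh multiplier is solved so the community-level PR:blh transcription
ratio is exactly 15. Housekeeping and retinal gene lengths are typical
bacterial CDS lengths (recA 1060, rplB 830, rpoB 4070, EF-Tu 1190, blh
900, crtB 930, crtY 1150 nt; PR ~750 nt).

What the generator does **not** model: overdispersion, GC/composition
bias, multi-mapping reads, genome-size variation, chimeras, sequencing
error, or primer-coverage bias. Passing recovery tests therefore
demonstrates that the estimators are correct *under their stated
assumptions* (one housekeeping copy per genome, proportional Poisson
recruitment), not that real libraries satisfy those assumptions.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates and compare the mean
estimate to analytic truth within three Monte-Carlo standard errors;
metagenome recovery runs at a depth giving thousands of expected reads
per housekeeping family (coverage 2.5 per nt), qPCR recovery at 0.15
cycles of Cq noise. The acceptance script averages four simulated
samples per statistic at depth 2000 — enough that single-run noise is
well below 1% while the whole script completes in seconds. Exact
scale-invariance tests use power-of-two factors so every floating-point
operation is exact. Pipeline outputs contain no timestamps, locale- or
path-order-dependent content; reruns of an unchanged configuration are
byte-identical.

## Known limitations

- No profile-HMM or domain-database screening: external searches enter
  through the hit-table importer only.
- Position mapping by pairwise alignment can mis-map in the presence of
  extreme divergence where an MSA with many intermediates might not;
  for sequences that pass the 82%-identity neighborhood of the
  reference panel this is immaterial.
- The 1.9 16S-copies-per-genome constant is a community-level
  assumption; per-taxon 16S copy numbers vary in reality.
- Greedy clustering is order-defined (length, then id); a different
  deterministic visit order can produce a different, equally valid
  partition near the threshold.
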