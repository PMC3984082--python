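# Methods

## Model and assumptions

A window of L biallelic SNPs is analysed as a closed system: each subject's
genotype is the ordered dosage vector v ∈ {0,1,2}^L of a designated counted
allele per site, and every genotype is assumed to be the elementwise sum of
exactly two binary haplotypes h₁ + h₂ = v drawn from a modest population
pool. The method's power comes from that pool being small relative to the
2^L possibilities — over ~200 kb windows in outbred human cohorts, a few
dozen haplotypes typically explain >99% of chromosomes. The procedure does
not assume Hardy-Weinberg equilibrium directly, but resolving conflicted
genotypes by the product f(h₁)·f(h₂) implicitly treats the two haplotypes
of a subject as independent draws, which is an HWE-style assumption; it
also relies on the cohort containing enough full homozygotes and
single-site heterozygotes to seed the identified list (roughly 16% or more
of subjects in practice).

The passes are described in the README. Two structural properties are
worth stating precisely:

- **Order invariance.** Clark's original algorithm processes subjects
  sequentially and its output depends on data order. Here every pass is a
  whole-cohort operation on the *set* of distinct genotype vectors
  (weighted by multiplicity): seeding collects all forced pairs at once,
  promotion adds all uniquely-implied strings of a round as a set, and
  frequencies are multiplicity-weighted counts. Permuting subjects yields
  bit-identical output (asserted by tests over random permutations).
- **Sum conservation.** Every emitted pair satisfies h₁ + h₂ = v exactly;
  the complement operation c = v − h is rejected unless all entries lie in
  {0,1}. There is no imputation and no approximate assignment.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `iteration_cap` | 4 | maximum promotion rounds during iterative identification (the initial decomposition is not counted; identification usually fixes in 2–3 rounds) |
| `rare_threshold` (m) | 9 | strings selected in fewer than m individuals trigger re-assessment; at an expected count of 9, a truly present haplotype is observed at least once with probability 1 − e⁻⁹ > 99.9%, so rarer survivors deserve a second look against commoner alternatives |
| `promotion_threshold` (τ) | 0.01 | a novel string carrying more than this share of non-conflicted identifications is promoted to identified status |
| nominal frequency f₀ | 0.5/H | assigned to listed strings never observed non-conflicted; H is the number of haplotype observations (2 per non-conflicted subject), so f₀ is half the smallest observable frequency and any observed string always outweighs a never-observed one |

All parameters are dimensionless; m counts individuals, not chromosomes.
The denominator convention for f₀ (haplotype observations rather than
distinct strings) was a genuinely open choice: "frequency" throughout the
procedure is a population proportion with denominator H, and using the
same denominator makes f₀ strictly smaller than every observable
frequency, which is the intended role of the floor.

## Frequency estimation

Frequencies used for conflict resolution come only from non-conflicted
decompositions (unambiguous, unique, indeterminate-unique), jointly over
cases and controls, and are re-estimated at each complete-list pass;
conflicted resolutions never feed back into the frequencies that resolve
them, which would otherwise let an early tie-break amplify itself. Final
reported frequencies are recomputed afterwards from all selected pairs.
An independent, phasing-free check is provided by the homozygote route:
under HWE a haplotype of frequency f is homozygous in f² of subjects, so
√(homozygote fraction) estimates f (implemented in
`structure.freq_from_homozygotes` and compared against simulated truth in
tests).

## Degenerate inputs and tie-breaks

- Conflicted candidates with exactly equal likelihood products are ordered
  by the concatenated pair text; the lexicographically smallest wins.
  This is arbitrary but deterministic, which order invariance requires.
- Homozygous candidate pairs use likelihood f(h)²; the product rule forces
  this.
- A genotype decomposable only as two never-implicated novel strings is
  reported `unresolved` (empty haplotype fields, excluded from association
  with a count in the report). Such genotypes are expected to be extremely
  rare in real panels when haplotype pairs combine near-randomly.
- Subjects with any missing call in the window are excluded from vector
  construction and listed in an exclusion report; no imputation. Whether a
  half-called genotype should count as missing is a chip-export question
  with no clean answer, so any partial call is treated as missing.
- A cohort with no unambiguous seeds at all cannot start (H = 0) and
  raises rather than guessing.
- Allele orientation flips a SNP only when the counted-allele frequency in
  controls strictly exceeds 0.5; a frequency of exactly 0.5 keeps the
  input orientation. Flipping is an involution. When the input is a bare
  manifest without the identity of the second allele, a flip is recorded
  in a `flipped` column (and the allele letters swapped only if an
  `other_allele` column is present); VCF input always carries both
  alleles.

## Association statistics

Carrier-category tests use the 3×2 table of 0/1/2 copies × case/control.
OR_het = (case₁/case₀)/(ctrl₁/ctrl₀) and OR_hom likewise for the 2-copy
class, with non-carriers as reference; significance is the 1-df Pearson
chi-square on the corresponding carrier-vs-non-carrier 2×2 table without
continuity correction. Zero divisors propagate as NaN, printed "na". No
multiple-testing adjustment is applied — outputs are raw per-target
statistics, with the number of targets available to the caller.

On the bundled published count tables this convention reproduces the
printed statistics (e.g. 114.7 for the risk-haplotype heterozygote test
and 7.6 for the recessive-haplotype homozygote test) to the printed
precision. One published chi-square value (55.5 for the HLA heterozygote
test) is not reproduced by Pearson's statistic, which gives 55.10 on the
same counts; no standard variant we tried yields 55.5, and we treat that
single entry as a probable typo rather than adopt a non-standard statistic.

The conditional (carrier-excluded) re-analysis removes all carriers of a
designated haplotype before re-tabulating another target. Its purpose is
diagnostic: haplotypes that merely co-occur less often with a true risk
haplotype show OR < 1 marginally but OR ≈ 1 conditionally, exposing the
"protection" as an artifact of negative linkage with the risk allele.

## Window merging

Two adjacent phased windows are linked through a third phased window that
bridges them (covering the tail of window 1 and the head of window 2). A
bridge haplotype links window-1 haplotype A to window-2 haplotype B when
its prefix equals A's tail and its suffix equals B's head; a valid linkage
must use both bridge haplotypes and both members of each window pair
exactly once. Exactly one consistent set of merged pairs is emitted as the
subject's long-range diplotype; several distinct sets flag `ambiguous`
(which necessarily happens when both window-1 haplotypes agree on the
whole overlap segment); none flags `inconsistent` (a phasing error in at
least one window). Chains longer than two windows merge left-to-right,
propagating flags. Crossover/recombination inference is out of scope.

## Family clustering

Families of identified strings are the connected components of the graph
joining strings at Hamming distance exactly 1. On the bundled 22-string
DRB1 inventory this reproduces the published 4-family partition exactly
(sizes 5, 8, 8 and 1). Components were chosen over motif-based grouping
because the distance-1 property is the published defining criterion and
components are the unique maximal sets satisfying it.

## The synthetic-data generator

`simulate.simulate_cohort` draws control diplotypes as independent pairs
from a fixed haplotype pool (HWE by construction) and case diplotypes by
rejection sampling against genotype relative risks for a designated risk
haplotype — geometric (1, w, w²), which keeps cases in HWE, or recessive
(1, 1, w). Rejection was preferred over analytic case-genotype frequencies
because it is exact for any weight scheme by construction. Missing data
are injected per call after truth is fixed. One seed determines
everything, with per-stage sub-streams spawned deterministically.

The default pool is the control-arm frequency spectrum of the DRB1 window
(15 haplotypes, frequencies 1–22%, normalized), with the DRB1\*1501-tagging
haplotype as the risk allele at w = 3 — matching the study system the
package models. The generator emulates a single-window panel with
unlinked, error-free calls; it does **not** model genotyping error,
population stratification, departure from HWE, LD decay within the window,
or recombination between haplotypes. Passing recovery tests therefore
demonstrates correctness of the algorithm under its own assumptions, not
robustness to those real-data complications.

## Problem sizes and test design

Simulation-backed tests use study-scale cohorts (900 + 900 subjects, the
scale at which the published window was analysed) for accuracy and
frequency recovery, three seeds, with 3% per-call missingness (which, at
L = 11, excludes ~28% of subjects — deliberately harsher than real panels
to exercise the exclusion path); and 20,000 per arm for odds-ratio
recovery under w = 3, where OR_het ≈ 3 within ~10% and OR_hom ≈ 9 within
~20% Monte-Carlo spread. The brute-force pair enumerator (2^(k−1)
unordered pairs for k heterozygous sites) serves as the independent oracle
for the decomposition search in 1,000 random-vector trials. Against
simulated truth the pipeline phases ≥ 99.8% of subjects correctly with
frequency errors under 1 percentage point; the residual errors are
conflicted genotypes whose true rare pair is, correctly under the model,
out-argued by a commoner pair of equal sum.

## Known limitations

- Windows with many heterozygous sites and few homozygotes (high local
  diversity) starve the unambiguous seeding step; the method is designed
  for short windows (≈3–24 SNPs) over regions of limited haplotype
  diversity.
- Conflict resolution picks a maximum-product point estimate; no
  posterior uncertainty is attached to an individual assignment beyond
  the recorded likelihood of the selected pair.
- Multi-allelic sites are rejected, not decomposed.
- The evaluator scores exact unordered-pair equality only; switch-error
  metrics are intentionally not implemented.
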