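# snpstring

Deterministic haplotype phasing over short windows of biallelic SNPs, with
haplotype-level case-control association statistics.

## The problem

Genome-wide association studies test SNPs one at a time, but a given SNP
allele often rides on several different haplotypes, only some of which carry
a causal variant. The association signal is then diluted: the tagging SNP
shows a higher allele frequency and a lower odds ratio than the causal
haplotype itself (a *synthetic association*). Recovering each subject's two
haplotypes over a window of nearby SNPs concentrates the signal back onto
the responsible haplotype — e.g. at the HLA-DRB1 locus, where the best
single SNP reaches an odds ratio of about 4 for homozygotes while the
underlying DRB1\*1501-tagging haplotype reaches about 7–9.

`snpstring` is for statistical geneticists who want a transparent,
reproducible alternative to probabilistic phasers (SHAPEIT, Beagle, EM
methods) on desk-scale case-control panels: every assignment is either
forced by the genotype or selected by an explicit frequency argument that
can be audited subject by subject.

## The method

Over a window of L biallelic SNPs, each subject's genotype is an ordered
ternary vector v ∈ {0,1,2}^L of counted-allele dosages, and each haplotype
("SNP-string") is a binary vector h ∈ {0,1}^L. Every genotype is the
elementwise sum of two haplotypes: v = h₁ + h₂. Phasing proceeds in
whole-cohort passes, extending Clark's subtraction algorithm:

1. **Unambiguous seeding.** A vector with no 1s forces a homozygous pair
   (h, h); a vector with exactly one 1 forces a pair differing only at that
   site. These seed the *identified* list.
2. **Iterative identification.** Each remaining vector is decomposed
   against the list. When a vector's only legitimate completion
   (c = v − h with all cᵢ ∈ {0,1}) requires exactly one unlisted string,
   that string is promoted to the list; passes repeat to a fixed point (at
   most 4 promotion rounds by default).
3. **Frequency-guided conflict resolution.** Haplotype frequencies f(h)
   are estimated from the non-conflicted decompositions only. A vector
   explainable by several listed pairs is assigned the pair maximizing
   f(h₁)·f(h₂); exact ties break lexicographically, so results are
   deterministic and independent of subject order.
4. **Complete list and pruning.** All remaining legitimate novel
   complements join a *complete* list at a nominal frequency
   f₀ = 0.5/H (half the smallest observable frequency, H = haplotype
   observations). Strings never selected are pruned until every survivor
   is selected at least once; novel strings carrying more than 1% of
   non-conflicted identifications are promoted to identified status.
5. **Rare-carrier re-assessment.** Subjects carrying strings selected in
   fewer than 9 individuals are re-examined against commoner alternatives
   (with 9 expected carriers, a truly present haplotype would be observed
   at least once with probability 1 − e⁻⁹ > 99.9%).

The package also provides carrier-category association statistics
(heterozygote and homozygote odds ratios against non-carriers, 1-df Pearson
chi-square, allelic frequencies, copy-number correlation, conditional
carrier-excluded re-analysis), Hamming-distance-1 family clustering of the
identified strings, merging of adjacent phased windows through an
overlapping bridge window, an HWE cohort simulator with geometric
(1, w, w²) or recessive genotype risks and known truth, and
phasing-concordance evaluation.

## Worked example

```python
from snpstring import SnpStringModel, simulate

# a study-scale cohort: 15-haplotype pool, risk haplotype at w = 3
spec = simulate.drb1_spec(n_cases=900, n_controls=900, w=3.0, seed=7)
cohort = simulate.simulate_cohort(spec)

res = SnpStringModel(cohort.matrix, cohort.manifest, orient=False).fit()
print(res.summary())
```

prints

```
SNP-string phasing results
==========================
subjects:             1800
  phased:             1800
  excluded (missing): 0
identification rounds: 1
classification counts:
  unambiguous  307
  unique       1459
  conflicted   34
inventory: 4 identified, 11 unambiguous (H = 3532, f0 = 1.42e-04)
top haplotypes (final frequency):
  01101100000   0.240  (unambiguous)
  10000100000   0.198  (unambiguous)
  10000011110   0.150  (unambiguous)
  ...
config: iteration_cap=4, m=9, tau=0.01
```

307 subjects had forced pairs, 1459 had a unique decomposition over the
inventory, and the 34 conflicted genotypes were resolved by the frequency
product rule. The risk haplotype `01101100000` is enriched in cases
(24% vs its 13% control pool frequency). Checking recovery against the
simulated truth and the injected risk:

```python
print(res.concordance_with(cohort.truth).fraction)   # 0.9994
a = res.association("01101100000")
print(round(a.or_het, 2), round(a.or_hom, 2))        # 3.36 9.43
```

The same objects are scriptable from the shell via the `snpstring` CLI
(`simulate`, `phase`, `associate`, `evaluate`, `merge`), each run leaving a
`run_manifest.json` with config, seed and input checksums.

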