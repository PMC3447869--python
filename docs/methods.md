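# Methods

## The model

`founderdrift` simulates the establishment of an isolated white-tailed
deer population founded in 1934 by three female and one male calf, as an
individual-based, overlapping-generations forward simulation. Each animal
is a record (sex, age in years, diploid genotype at 14 unlinked
microsatellite loci, parent ids). Allele labels are opaque positive
integers; repeat sizes, mutation, selection, migration and density
dependence are all absent, so the only genetic forces are the founder
sampling and drift through the pedigree.

### Yearly cycle

Time steps are years. Steps 0–4 are scripted from the documented
enclosure phase: the four founders arrive as calves, nobody dies, and two
designated females each bear one calf sired by the single male at steps 3
and 4. The post-birth population sizes are deterministic: 4, 4, 4, 6, 8.
The sexes of the step-3 calves are treated as one female and one male by
default (they were recorded but not published); the step-4 calves' sexes
are random. Swapping the step-3 sex assignment for its alternatives moves
the mean final heterozygosity by well under 0.01 — within a couple of
replicate-sampling standard errors — and the test suite checks this
insensitivity directly.

From step 5 each year proceeds as: (1) every female of age ≥ 1 is paired
with one male drawn uniformly with replacement from males of age ≥ 1 and
bears 0, 1 or 2 fawns per the age-specific fecundity schedule; each fawn
is female with probability 0.5 and receives one uniformly chosen allele
from each parent at every locus, independently across loci; (2) the
post-birth ("autumn census") population size is recorded; (3) every
animal survives the winter as an independent Bernoulli trial with
probability 0.75 (fawns), 0.80 (yearlings) or 0.85 (older); (4) ages
increment, and animals passing the 16-year lifespan cap die
deterministically. If either sex is absent, no fawns are produced; a
replicate is flagged extinct — and excluded from all summaries — if at the
horizon it has no individuals or no individuals of one sex.

Scenario C adds, at the start of step 15 (the documented 1949 restocking
attempt), one male and three females of age 1, each heterozygous at every
locus with allele labels disjoint from everything already present (8
novel alleles per locus).

### Founder genotypes

Founder construction brackets the unknown truth. All schemes display an
exact per-locus allele count `k`:

- `max_het` (A1): the `k` labels are round-robined over the 8 gene copies
  (as even a spectrum as the constraint allows) and paired consecutively,
  so every founder is heterozygous everywhere. Beyond the count and
  full-heterozygosity constraints the allele multiplicities are not
  identified; the even spectrum is a reproducible choice, and the A1/A2
  comparison shows the final heterozygosity is insensitive to it.
- `min_het` (A2): `max(0, k − 4)` founders are heterozygous with two
  unique alleles each; the rest are homozygous for the remaining labels,
  recycling labels if they run short. The resulting founder-mean
  heterozygosity equals the analytic minimum `Σ max(0, k − 4) / (4·14)`
  = 22/56 ≈ 0.39 for the observed allele counts, which a brute-force
  assignment search confirms for all small cases.
- `max_ar` (B): all 8 gene copies distinct (`k = 8` forced).

### Parameters and calibration

| parameter | default | units | rationale |
|---|---|---|---|
| survival (fawn / yearling / adult) | 0.75 / 0.80 / 0.85 | per winter | documented model values |
| maximum lifespan | 16 | years | documented model value |
| fawn sex ratio | 0.5 | — | fair Bernoulli |
| breeding age (both sexes) | ≥ 1 | years | yearling does breed at reduced rates; configurable |
| fecundity, age 1 | (0.60, 0.35, 0.05) | P(0/1/2 fawns) | calibrated, see below |
| fecundity, age ≥ 2 | (0.20, 0.50, 0.30) | P(0/1/2 fawns) | calibrated, see below |
| horizon | 45 | years | establishment period of interest |
| replicates | 1000 | — | published replication count |

The fecundity schedule is the calibration dial. The original age-specific
0/1/2-fawn probabilities are not available, but the census record is:
~12 animals in 1939 (step 5), 15–20 in 1941, 30–40 in 1945, 90–100 in
1948, ~200 in 1956 (step 22), with the ~1000 figure for 1961 widely
considered unreliable — and deliberately *not* matched, since vital rates
high enough to reach it would understate drift. We fitted the two
expected litter sizes (yearling, adult) by least squares in log space
between the deterministic expectation of the model's trajectory (an
age-structured recursion seeded with the scripted step-5 state) and the
census anchors, then rounded to the tabled probabilities. The calibrated
expectation passes 13 at step 5, 63 at step 14, 228 at step 22 and 506 at
step 27, i.e. within a factor of 2 of every anchor it is fitted to and
well below 1000 at step 27. Calibration used the census only; the genetic
outcomes were computed afterwards.

With these rates a replicate reaches roughly 10⁴ animals by step 45, the
population state is stored column-wise in NumPy arrays, and the whole
yearly update (fecundity draws, vectorised Mendelian transmission,
survival thinning) costs a few milliseconds per year, so the default
four-scenario, 1000-replicate analysis runs in a couple of minutes on one
CPU.

### Randomness

Each replicate owns a `numpy` Generator seeded from
`SeedSequence(scenario_seed).spawn(n_replicates)`; replicates are
therefore independent and the whole scenario summary is reproducible from
the single scenario seed. Identical seeds give bit-identical replicate
results.

## Diversity statistics

Expected heterozygosity is Nei's unbiased gene diversity
`ĥ = n/(n−1) (1 − Σ p̂ᵢ²)` over `n` sampled gene copies, clipped to
[0, 1]; it requires `n ≥ 2`. Allelic richness is the raw distinct-allele
count: the two empirical samples are both exactly 72 complete-case
individuals, so rarefaction to the common sample size is the identity.
Simulated population heterozygosity is instead the mean over living
individuals of the fraction of heterozygous loci (a census quantity, not
a sample estimate), and simulated allelic richness is the mean over loci
of distinct alleles carried by the living population. Missing data use
the reserved sentinel 0; complete-case filtering precedes any
subsampling, and per-locus statistics drop missing individuals at that
locus only.

The two-population comparison is a Mann–Whitney U test on the 14
per-locus values: tie-corrected normal approximation without continuity
correction (the convention of the mainstream commercial packages), Z
signed negative when the first sample has the smaller mean rank, one-tailed
p = Φ(Z). On the packaged per-locus values this gives Z = −2.565
(p = 0.0052) for allelic richness and Z = −1.654 (p = 0.0491) for expected
heterozygosity. For tiny samples the appropriate exact oracle is the
permutation *mid-p* (P(S < obs) + ½ P(S = obs)): the no-continuity normal
approximation estimates that quantity, and the test suite checks agreement
within 0.05 for n ≤ 5; the inclusive tail probability P(S ≤ obs) can
differ from the approximation by more at extreme configurations.

Display rounding follows the source table: three decimals for
heterozygosities, two for over-loci means.

## Classic-theory contrast

`theory.retention` implements `Π (1 − 1/(2Neᵢ))` and
`theory.heterozygosity_decay` the per-step decay, which is strictly
linear in H₀. The per-year effective sizes behind the "~75% retained"
figure are not available, so `reconstructed_ne_schedule` ships a clearly
labelled reconstruction: census sizes geometrically interpolated between
the historical anchors, scaled by a single factor (Ne = c·N, c solved by
bisection) so the 45-step retention is exactly 0.75. The factor exceeds 1,
reflecting that with overlapping generations a yearly headcount
understates the per-year effective size. Under that schedule H₀ = 0.742
decays to 0.56 and H₀ = 0.39 to 0.29 — the wide classic-theory spread that
the individual-based model's founder-insensitivity (A1 vs A2 differing by
< 0.01) is contrasted against. Whether schedule entries are years or
generations is the caller's choice; per-year is the default used here.

## Synthetic genotype generator

`sample_genotypes` draws each allele independently from per-locus
frequencies (Hardy–Weinberg, linkage equilibrium) and masks genotype
slots missing independently at a fixed rate. `finland_like_profile`
builds a 14-locus profile whose allele counts equal the observed Finnish
allelic richness and whose frequencies are solved — one major allele plus
an even remainder, fitted by bisection — so that the *unbiased* expected
heterozygosity at 72 diploids matches the observed per-locus values
(the published values are unbiased estimates, hence that convention).
The profile is structure-matching only: the real per-locus frequency
table is unpublished, so agreement of any statistic with the synthetic
profile shows estimator correctness under HWE, not agreement with the
real frequency spectrum. Genotyping error, null alleles, allelic dropout
and stutter are not simulated, so the generator says nothing about
robustness to those artefacts.

## Known limitations and deliberate divergences

- **Scenario C.** Under the stated mechanism — four reproducing yearlings
  with eight novel alleles per locus entering a ~60–100 animal population
  that then grows at λ ≈ 1.2 — each single-copy novel allele founds a
  supercritical branching process and survives with probability ≈ 0.5.
  Our runs accordingly keep ~4 novel alleles per locus (final AR ≈ 9.0,
  H ≈ 0.70). The originally reported scenario-C effect (+0.10 alleles,
  +0.005 H over A1, with an AR upper percentile exactly at the founder
  value 5.36) would require novel-lineage survival of ~1%, which is not
  attainable under any census-compatible demography; it is consistent
  with the introduced cohort rarely or never reproducing. We implement
  the mechanism as stated and report the divergence rather than matching
  the numbers.
- Final allelic richness under scenario B runs ~0.4 alleles above the
  original report (6.4 vs 6.0) with the census-calibrated demography; the
  uniform upward shift of the whole replicate distribution suggests the
  original model had slightly stronger early drift than our calibration
  family produces. We do not select among equally census-consistent
  calibrations by their genetic output.
- The establishment record is deterministic in the model; any
  undocumented mortality or reproduction 1934–1938 is absorbed into the
  stochastic phase.
- "45 years after 1934" is nominally 1979, not 1975 as sometimes stated
  alongside it; the model simply runs 45 time steps, by which point the
  population is large and heterozygosity has plateaued.
- Passing tests demonstrate internal consistency (estimators, Mendelian
  transmission, demographic moments, reproducibility) and agreement with
  the published summary values where attainable — not that the real
  founders matched any scenario, nor that mutation (which the model
  excludes and which may matter at current population sizes) is
  negligible for rare alleles.
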