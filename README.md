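# founderdrift

How much genetic diversity does a wild population keep when it is founded
by just four animals? The Finnish white-tailed deer (*Odocoileus
virginianus*) population descends from three females and one male released
in 1934 and has lived in complete isolation ever since, growing into the
tens of thousands — a rare natural experiment on the founder effect.
`founderdrift` is a Python package for analysing that experiment: it
computes microsatellite diversity statistics for the empirical samples,
simulates the introduction forward in time individual by individual, and
contrasts the simulation with classic drift theory.

It is aimed at population geneticists and conservation modellers who want
an explicit, genealogy-tracking alternative to Wright–Fisher-style
heterozygosity bookkeeping for iteroparous species with overlapping
generations.

## What it computes

**Diversity statistics** (`founderdrift.popgen`). For diploid multi-locus
genotype samples: Nei's unbiased gene diversity
*ĥ = n/(n−1) (1 − Σ pᵢ²)*, allelic richness *A_R* (distinct-allele count;
both samples here hold 72 complete cases, so rarefaction is the identity),
observed heterozygosity, over-loci means, and a tie-corrected one-tailed
Mann–Whitney *U* comparison (normal approximation, no continuity
correction) between the per-locus statistics of two populations. The
published per-locus values for the Finnish and Oklahoma samples ship as
packaged data.

**The individual-based model** (`founderdrift.ibm`). Every animal carries
a sex, an age and a 14-locus diploid genotype. Years 0–4 (the enclosure
phase) are scripted from the documented history — no deaths, two females
each bearing one calf sired by the single male in years 3 and 4, giving
population sizes 4, 4, 4, 6, 8. From year 5 every breeding-age female
pairs with a uniformly chosen male and bears 0/1/2 fawns per an
age-specific fecundity schedule; fawns inherit one uniform allele per
parent per locus; over-winter survival is 0.75/0.80/0.85
(fawn/yearling/adult) and nobody lives past 16. No mutation, no density
dependence. Founder genotypes follow four bracketing scenarios:

| scenario | founder genotypes | H₀ | AR₀ |
|---|---|---|---|
| A1 | observed allele counts, all founders heterozygous | 1 | 5.36 |
| A2 | observed allele counts, minimal heterozygosity | 0.39 | 5.36 |
| B | 8 distinct alleles per locus | 1 | 8 |
| C | as A1 + a 1949 release of 4 novel-allele heterozygotes | 1 | 5.36 |

Replicated runs (1000 by default) summarise final population
heterozygosity and allelic richness with 2.5/97.5 percentile bands,
excluding replicates that went extinct.

**Classic theory** (`founderdrift.theory`). The textbook decay
*H_t = H₀ · Πᵢ (1 − 1/(2Neᵢ))*, which is linear in H₀ — precisely the
property the individual-based model does *not* share, and the reason the
two predictions diverge when founder diversity is unknown.

**Synthetic data** (`founderdrift.synthetic`). Hardy–Weinberg genotype
samples drawn from per-locus allele frequencies, including a
structure-matched "Finland-like" profile, so every statistic is testable
without the unpublished raw genotypes.

## Worked example

```python
import founderdrift as fd

model = fd.IntroductionModel.from_scenario("A1", n_replicates=1000, seed=1)
results = model.simulate()
print(results.summary())
```

```
Scenario A1: 1000 replicates (13 extinct, excluded)
  final heterozygosity  H  = 0.643 (0.521-0.715)
  final allelic richness AR = 4.56 (3.26-5.36)
  mean final population size = 9902
```

Despite the four-founder bottleneck, the simulated population retains a
mean heterozygosity of 0.64 after 45 years — close to the 0.692 observed
in the field sample, and far above the ≈0.55 that classic theory predicts
for a source-like founder heterozygosity of 0.742. The brackets are the
2.5/97.5 percentiles over replicates; the 13 extinct replicates (demographic
bad luck in the small early population) are excluded from the summary.

The same numbers are available from the shell, along with the empirical
comparison and the classic-theory contrast:

```sh
founderdrift reproduce --replicates 1000 --seed 1 --outdir out/
founderdrift stats my_genotypes.gen          # Genepop or wide CSV input
founderdrift run --scenario B --replicates 1000 --seed 7 --out out/
founderdrift classic --h0 0.742
founderdrift simulate-data --n 72 --seed 3
```

`reproduce` prints, for example (200 replicates shown for brevity):

```
Observed diversity (72 individuals, 14 loci):
  Finland  H_E = 0.692, A_R = 5.36
  Oklahoma H_E = 0.742, A_R = 9.07
  Mann-Whitney A_R: Z = -2.565, one-tailed p = 0.0052
  Mann-Whitney H_E: Z = -1.654, one-tailed p = 0.0491

Classic theory (reconstructed Ne schedule, retention 0.75):
  H_0 = 0.742 -> H_45 = 0.56
  H_0 = 1.000 -> H_45 = 0.75
  H_0 = 0.390 -> H_45 = 0.29

Simulated scenarios (200 replicates each):
  A1: H = 0.640 (0.491-0.716) vs published 0.631; AR = 4.49 vs 4.40; 1 extinct
  A2: H = 0.638 (0.510-0.720) vs published 0.630; AR = 4.56 vs 4.38; 1 extinct
  B: H = 0.740 (0.649-0.801) vs published 0.725; AR = 6.37 vs 6.01; 3 extinct
  C: H = 0.695 (0.602-0.779) vs published 0.636; AR = 8.94 vs 4.50; 0 extinct
```

The A1/A2 rows illustrate the study's central point: the final
heterozygosity is essentially independent of the founders' own
heterozygosity (0.640 vs 0.638), whereas classic theory spreads from 0.29
to 0.75 over the same range of H₀. See `docs/methods.md` for the model
assumptions, the demographic calibration, and a discussion of scenario C,
where this implementation deliberately diverges from the published
numbers.

Every command writes a `manifest.json` (config snapshot, seed, version,
output digests); re-running with the same manifest inputs reproduces the
outputs bit-identically.

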