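"""The individual-based simulator: transmission, demography, replicates."""
import numpy as np
import pytest
from scipy import stats as sps

from founderdrift.founders import IntroductionEvent
from founderdrift.ibm import (
    FEMALE,
    MALE,
    Population,
    ScenarioConfig,
    VitalRates,
    annual_step,
    individual_heterozygosity,
    population_AR,
    population_H,
    run_replicate,
    scenario_config,
    scripted_establishment,
    transmit,
)


class TestTransmit:
    def test_homozygous_cross_is_deterministic(self, rng):
        aa = np.array([[1, 1]])
        assert np.array_equal(transmit(aa, aa, rng), aa)

    def test_ab_x_cd_uniform_over_four_outcomes(self, rng):
        mother = np.array([[1, 2]])
        father = np.array([[3, 4]])
        counts = {}
        for _ in range(10_000):
            off = tuple(transmit(mother, father, rng)[0])
            counts[off] = counts.get(off, 0) + 1
        assert set(counts) == {(1, 3), (1, 4), (2, 3), (2, 4)}
        chi2 = sps.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3  # consistent with uniform 1/4 each

    def test_offspring_alleles_subset_of_parents(self, rng):
        mother = np.array([[1, 2], [5, 5], [7, 8]])
        father = np.array([[3, 4], [5, 6], [7, 7]])
        for _ in range(50):
            off = transmit(mother, father, rng)
            for j in range(3):
                assert off[j, 0] in mother[j]
                assert off[j, 1] in father[j]

    def test_locus_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            transmit(np.ones((3, 2)), np.ones((2, 2)), rng)


def test_individual_heterozygosity_fractions():
    assert individual_heterozygosity(np.array([[1, 1], [2, 2]])) == 0.0
    g = np.column_stack([np.arange(14), np.arange(14) + 100])
    assert individual_heterozygosity(g) == 1.0
    half = np.array([[1, 2]] * 7 + [[3, 3]] * 7)
    assert individual_heterozygosity(half) == 0.5


def _population(genotypes, sexes, ages):
    return Population(
        np.asarray(genotypes), np.asarray(sexes, dtype=np.int8),
        np.asarray(ages, dtype=np.int16),
    )


class TestPopulationStatistics:
    def test_population_H_mean_and_duplication_invariance(self):
        het = [[1, 2]]
        hom = [[3, 3]]
        pop = _population([het, hom], [FEMALE, MALE], [2, 2])
        assert population_H(pop) == 0.5
        doubled = _population([het, hom, het, hom], [FEMALE, MALE] * 2, [2] * 4)
        assert population_H(doubled) == 0.5

    def test_population_AR_mean_over_loci(self):
        pop = _population([[[1, 2], [1, 1]], [[3, 3], [1, 1]]], [FEMALE, MALE], [2, 2])
        assert population_AR(pop) == pytest.approx((3 + 1) / 2)
        single = _population([[[5, 5], [5, 5]]], [FEMALE], [2])
        assert population_AR(single) == 1.0

    def test_empty_population_errors(self):
        empty = _population(np.empty((0, 1, 2)), [], [])
        with pytest.raises(ValueError):
            population_H(empty)
        with pytest.raises(ValueError):
            population_AR(empty)


class TestScriptedEstablishment:
    def test_census_trajectory_and_genealogy(self, rng):
        config = scenario_config("A1", n_replicates=1)
        from founderdrift.founders import build_founders

        founders = build_founders(config.founder_spec)
        pop, traj = scripted_establishment(founders, config, rng)
        assert traj == [4, 4, 4, 6, 8]
        calves = [ind for ind in pop.individuals() if ind.father_id is not None]
        assert len(calves) == 4
        male_id = 3  # founders are 3 females then the male
        assert all(c.father_id == male_id for c in calves)
        assert {c.mother_id for c in calves} == {0, 1}  # the two documented dams
        # calf alleles are drawn from the founder pool
        founder_pool = [set(founders[:, j, :].ravel()) for j in range(founders.shape[1])]
        for c in calves:
            for j in range(14):
                assert set(c.genotype[j]) <= founder_pool[j]

    def test_ages_entering_first_stochastic_year(self, rng):
        config = scenario_config("A1", n_replicates=1)
        from founderdrift.founders import build_founders

        pop, _ = scripted_establishment(build_founders(config.founder_spec), config, rng)
        ages = sorted(pop.age.tolist())
        assert ages == [1, 1, 2, 2, 5, 5, 5, 5]  # 1938/1937 calves, founders in 1939

    def test_short_horizon_rejected(self, rng):
        with pytest.raises(ValueError):
            scenario_config("A1", horizon=4)


class TestAnnualStep:
    def test_no_mortality_no_fecundity_is_static_until_age_cap(self, rng):
        vr = VitalRates(survival_newborn=1, survival_yearling=1, survival_adult=1,
                        fecundity_schedule={0: (1, 0, 0), "adult": (1, 0, 0)})
        pop = _population([[[1, 2]]] * 6, [FEMALE] * 3 + [MALE] * 3, [10] * 6)
        for _ in range(6):  # ages 10 -> 16, no one crosses the cap
            pop, census = annual_step(pop, vr, rng)
            assert census == 6 and pop.size == 6
        pop, _ = annual_step(pop, vr, rng)  # past age 16: deterministic death
        assert pop.size == 0

    def test_zero_survival_extinguishes_in_one_step(self, rng):
        vr = VitalRates(survival_newborn=0, survival_yearling=0, survival_adult=0)
        pop = _population([[[1, 2]]] * 10, [FEMALE] * 5 + [MALE] * 5, [3] * 10)
        pop, _ = annual_step(pop, vr, rng)
        assert pop.size == 0

    def test_litter_size_moments_match_schedule(self, rng):
        p0, p1, p2 = 0.2, 0.5, 0.3
        vr = VitalRates(survival_newborn=1, survival_yearling=1, survival_adult=1,
                        fecundity_schedule={0: (1, 0, 0), "adult": (p0, p1, p2)})
        n_f = 10_000
        geno = [[[1, 1]]] * (n_f + 1)
        pop = _population(geno, [FEMALE] * n_f + [MALE], [3] * (n_f + 1))
        _, census = annual_step(pop, vr, rng)
        births = census - (n_f + 1)
        mean_litter = births / n_f
        expected = p1 + 2 * p2
        var = (p1 + 4 * p2) - expected**2
        se = np.sqrt(var / n_f)
        assert abs(mean_litter - expected) < 3 * se

    def test_no_males_means_no_births(self, rng):
        vr = VitalRates()
        pop = _population([[[1, 2]]] * 5, [FEMALE] * 5, [3] * 5)
        _, census = annual_step(pop, vr, rng)
        assert census == 5


class TestRunReplicate:
    def test_same_seed_bit_identical(self):
        config = scenario_config("A1", n_replicates=1, horizon=20)
        a = run_replicate(config, seed=99)
        b = run_replicate(config, seed=99)
        assert np.array_equal(a.trajectory, b.trajectory)
        assert a.final_H == b.final_H and a.final_AR == b.final_AR

    def test_minimal_horizon_runs_one_stochastic_year(self):
        config = scenario_config("A1", n_replicates=1, horizon=5)
        rep = run_replicate(config, seed=5)
        assert len(rep.trajectory) == 6
        assert list(rep.trajectory[:5]) == [4, 4, 4, 6, 8]

    def test_deterministic_growth_matches_closed_form(self):
        """All-female sexing, full survival, one fawn per female per year:
        every female beyond her birth year breeds, so the female count
        doubles annually and the census is 7 * 2**(t-4) + 1 (the male)."""
        vr = VitalRates(
            survival_newborn=1, survival_yearling=1, survival_adult=1,
            fecundity_schedule={0: (1, 0, 0), 1: (0, 1, 0), "adult": (0, 1, 0)},
            female_prob=1.0,
        )
        config = scenario_config(
            "A1", n_replicates=1, horizon=10, vital_rates=vr,
            scripted_calf_sexes=(FEMALE, FEMALE),
        )
        rep = run_replicate(config, seed=0)
        expected = [4, 4, 4, 6, 8] + [7 * 2 ** (t - 4) + 1 for t in range(5, 11)]
        assert list(rep.trajectory) == expected

    def test_allelic_closure_and_monotone_ar(self):
        config = scenario_config("A1", n_replicates=1, horizon=25,
                                 record_genetic_trajectory=True)
        rep = run_replicate(config, seed=17)
        ar = rep.AR_trajectory
        assert np.all(np.diff(ar[~np.isnan(ar)]) <= 1e-12)  # drift only loses alleles
        assert np.nanmax(ar) <= np.mean(config.founder_spec.ar_per_locus) + 1e-12

    def test_second_introduction_adds_disjoint_alleles(self):
        config = scenario_config("C", n_replicates=1, horizon=16,
                                 record_genetic_trajectory=True)
        rep = run_replicate(config, seed=3)
        # AR jumps by at most 8 per locus at the introduction step
        assert rep.AR_trajectory[15] > rep.AR_trajectory[14]
        assert rep.AR_trajectory[15] <= rep.AR_trajectory[14] + 8


class TestScenarioConfigs:
    def test_presets(self):
        assert scenario_config("A2").founder_spec.scheme == "min_het"
        b = scenario_config("B")
        assert b.founder_spec.ar_per_locus == (8,) * 14
        c = scenario_config("C")
        assert isinstance(c.second_introduction, IntroductionEvent)
        assert c.second_introduction.time_step == 15
        with pytest.raises(ValueError):
            scenario_config("D")

    def test_vital_rates_validation(self):
        with pytest.raises(ValueError):
            VitalRates(survival_adult=1.2)
        with pytest.raises(ValueError):
            VitalRates(fecundity_schedule={0: (0.5, 0.2, 0.2)})


class TestScriptedSexSensitivity:
    def test_final_h_insensitive_to_1937_calf_sexes(self):
        """The unpublished sexes of the two 1937 calves barely move final H."""
        means = []
        for sexes in ((FEMALE, MALE), (MALE, FEMALE)):
            from founderdrift.ibm import run_scenario

            config = scenario_config("A1", n_replicates=300, seed=11,
                                     scripted_calf_sexes=sexes)
            means.append(run_scenario(config).mean_H)
        assert abs(means[0] - means[1]) < 0.02
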