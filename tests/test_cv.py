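import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cmapcv.cv import (
    BIN_CENTERS,
    Axon,
    CVHistogram,
    allowed_cvs,
    apply_conduction_block,
    apply_demyelination,
    histogram_from_population,
    normal_histogram,
    population_from_histogram,
)


class TestNormalHistogram:
    def test_reference_counts(self):
        h = normal_histogram()
        assert h.total == 200
        assert h.count_at(51) == 42
        assert h.count_at(63) == 1
        assert h.count_at(49) == 39
        assert h.count_at(37) == 1
        assert h.count_at(0) == 0
        assert h.count_at(11) == 0

    def test_bin_layout(self):
        h = normal_histogram()
        assert list(h.bin_centers) == [0] + list(range(11, 64, 2))
        assert len(h.bin_centers) == 28


class TestPopulationConversion:
    def test_expand_normal_model(self, normal_population):
        pop = normal_population
        assert len(pop) == 200
        assert pop.n_blocked == 0
        assert np.all(pop.normal_cvs() == pop.forearm_cvs())

    def test_single_axon_histogram(self):
        counts = np.zeros(28, dtype=int)
        counts[BIN_CENTERS.tolist().index(53)] = 1
        pop = population_from_histogram(CVHistogram(counts))
        assert len(pop) == 1
        assert pop.axons[0] == Axon(53, 53, False)

    def test_round_trip_preserves_cv_multiset(self, normal_population):
        h = histogram_from_population(normal_population)
        assert np.array_equal(h.counts, normal_histogram().counts)
        pop2 = population_from_histogram(h)
        assert sorted(a.forearm_cv for a in pop2.axons) == sorted(
            a.forearm_cv for a in normal_population.axons
        )

    def test_blocked_bin_must_be_empty(self):
        counts = np.zeros(28, dtype=int)
        counts[0] = 1
        with pytest.raises(ValueError):
            population_from_histogram(CVHistogram(counts))


class TestAllowedCVs:
    def test_pattern4_mild_example(self):
        assert allowed_cvs(4, 53) == (45, 47, 49, 51, 53)

    def test_pattern6_two_distribution_example(self):
        assert allowed_cvs(6, 53) == (11, 13, 15, 17, 19, 45, 47, 49, 51, 53)

    def test_pattern1_degenerate_lower_bound(self):
        assert allowed_cvs(1, 37) == tuple(range(11, 38, 2))

    def test_fixed_range_patterns(self):
        assert allowed_cvs(2, 63) == (11, 13, 15, 17, 19)
        assert allowed_cvs(3, 41) == tuple(range(21, 36, 2))

    def test_pattern5_moderate2(self):
        assert allowed_cvs(5, 53) == tuple(range(33, 54, 2))

    @pytest.mark.parametrize("cv", [36, 35, 65, 40])
    def test_invalid_cv_rejected(self, cv):
        with pytest.raises(ValueError):
            allowed_cvs(1, cv)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            allowed_cvs(7, 53)


class TestDemyelination:
    def test_pattern2_forces_severe_range(self, normal_population):
        pop = apply_demyelination(normal_population, 2, seed=5)
        assert set(pop.forearm_cvs()) <= {11, 13, 15, 17, 19}
        assert np.array_equal(pop.normal_cvs(), normal_population.normal_cvs())

    def test_deterministic_given_seed(self, normal_population):
        a = apply_demyelination(normal_population, 1, seed=42)
        b = apply_demyelination(normal_population, 1, seed=42)
        assert np.array_equal(a.forearm_cvs(), b.forearm_cvs())

    @given(st.integers(1, 6), st.integers(0, 10_000))
    def test_draws_stay_in_allowed_set(self, pattern, seed):
        pop = population_from_histogram(normal_histogram())
        out = apply_demyelination(pop, pattern, seed=seed)
        for axon in out.axons:
            assert axon.forearm_cv in allowed_cvs(pattern, axon.normal_cv)

    def test_block_must_come_after_slowing(self, normal_population):
        blocked = apply_conduction_block(normal_population, 0.4, seed=0)
        with pytest.raises(ValueError):
            apply_demyelination(blocked, 1, seed=0)

    def test_weighted_draws_respect_point_mass(self, normal_population):
        pop = apply_demyelination(normal_population, 2, seed=0, weights={11: 1.0})
        assert set(pop.forearm_cvs()) == {11}

    def test_pattern4_draws_uniform_chi_square(self):
        # one axon at 53 m/s, 10,000 independent slowing draws
        counts = np.zeros(28, dtype=int)
        counts[BIN_CENTERS.tolist().index(53)] = 1
        pop = population_from_histogram(CVHistogram(counts))
        draws = [
            apply_demyelination(pop, 4, seed=s).axons[0].forearm_cv
            for s in range(10_000)
        ]
        values, observed = np.unique(draws, return_counts=True)
        assert set(values) == {45, 47, 49, 51, 53}
        chi2 = stats.chisquare(observed).statistic
        assert chi2 < stats.chi2.ppf(0.999, df=4)
        assert np.allclose(observed / 10_000, 0.2, atol=0.02)


class TestConductionBlock:
    def test_probability_zero_blocks_nothing(self, normal_population):
        assert apply_conduction_block(normal_population, 0.0, seed=1).n_blocked == 0

    def test_probability_one_blocks_all(self, normal_population):
        pop = apply_conduction_block(normal_population, 1.0, seed=1)
        assert pop.n_blocked == 200

    def test_invalid_probability(self, normal_population):
        with pytest.raises(ValueError):
            apply_conduction_block(normal_population, 1.5, seed=0)

    def test_blocked_axons_keep_cvs(self, normal_population):
        pop = apply_conduction_block(normal_population, 0.4, seed=3)
        assert np.array_equal(pop.forearm_cvs(), normal_population.forearm_cvs())

    def test_mean_blocked_fraction(self, normal_population):
        total = sum(
            apply_conduction_block(normal_population, 0.4, seed=s).n_blocked
            for s in range(2000)
        )
        assert abs(total / (2000 * 200) - 0.4) < 0.01


class TestHistogramFromPopulation:
    def test_all_blocked_population(self, normal_population):
        pop = apply_conduction_block(normal_population, 1.0, seed=0)
        h = histogram_from_population(pop)
        assert h.counts[0] == 200
        assert h.counts[1:].sum() == 0

    @given(st.integers(1, 6), st.integers(0, 10_000), st.booleans())
    def test_counts_conserved(self, pattern, seed, with_block):
        pop = population_from_histogram(normal_histogram())
        pop = apply_demyelination(pop, pattern, seed=seed)
        if with_block:
            pop = apply_conduction_block(pop, 0.4, seed=seed + 1)
        h = histogram_from_population(pop)
        # brute-force recount
        assert h.total == len(pop) == 200
        assert h.counts[0] == pop.n_blocked


class TestValidation:
    def test_axon_cv_bounds(self):
        with pytest.raises(ValueError):
            Axon(36, 36)
        with pytest.raises(ValueError):
            Axon(53, 9)

    def test_histogram_shape_and_sign(self):
        with pytest.raises(ValueError):
            CVHistogram(np.zeros(27, dtype=int))
        bad = np.zeros(28, dtype=int)
        bad[3] = -1
        with pytest.raises(ValueError):
            CVHistogram(bad)

    def test_histogram_csv_round_trip(self, tmp_path):
        h = normal_histogram()
        p = tmp_path / "h.csv"
        h.to_csv(p)
        assert np.array_equal(CVHistogram.from_csv(p).counts, h.counts)
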