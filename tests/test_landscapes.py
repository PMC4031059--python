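"""NK and Rough Mt. Fuji landscape construction and distribution summaries."""

import numpy as np
import pytest
from scipy import integrate

import ridgewalk as rw
from ridgewalk.genotype import enumerate_genotypes
from ridgewalk.landscapes import LOW_TAIL_MASS, NKLandscape, RMFLandscape


class TestNKConstruction:
    def test_table_sizes_follow_k(self, rng):
        assert rw.make_nk_landscape(3, 0, rng=rng).contributions.shape == (3, 2)
        assert rw.make_nk_landscape(3, 2, rng=rng).contributions.shape == (3, 8)

    def test_neighborhoods_are_distinct_other_loci(self, rng):
        lnd = rw.make_nk_landscape(15, 10, rng=rng)
        for i in range(15):
            nbrs = lnd.neighborhoods[i]
            assert len(set(nbrs.tolist())) == 10
            assert i not in nbrs

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            rw.make_nk_landscape(5, 5, rng=rng)

    def test_same_seed_reproduces_landscape_exactly(self):
        a = rw.make_nk_landscape(10, 4, rng=np.random.default_rng(7))
        b = rw.make_nk_landscape(10, 4, rng=np.random.default_rng(7))
        assert np.array_equal(a.neighborhoods, b.neighborhoods)
        assert np.array_equal(a.contributions, b.contributions)

    def test_json_round_trip_preserves_fitness(self, small_nk):
        clone = NKLandscape.from_json(small_nk.to_json())
        assert np.allclose(clone.fitness_table(), small_nk.fitness_table())


class TestNKFitness:
    def test_constant_contributions_give_constant_fitness(self):
        lnd = NKLandscape(L=4, K=1,
                          neighborhoods=[[1], [2], [3], [0]],
                          contributions=np.full((4, 4), 0.7),
                          c_min=0.1, c_max=1.0)
        assert np.allclose(lnd.fitness_table(), 0.7)

    def test_two_locus_geometric_mean_by_hand(self):
        # locus 0 contributes 1.0 (allele 0) or 0.25 (allele 1); locus 1 always 1.0
        lnd = NKLandscape(L=2, K=0, neighborhoods=np.empty((2, 0), dtype=int),
                          contributions=[[1.0, 0.25], [1.0, 1.0]],
                          c_min=0.1, c_max=1.0)
        assert lnd.fitness((1, 0)) == pytest.approx(0.5)
        assert lnd.fitness((0, 0)) == pytest.approx(1.0)

    def test_matches_brute_force_recomputation_from_raw_tables(self, rng):
        lnd = rw.make_nk_landscape(6, 3, rng=rng)
        for g in enumerate_genotypes(6):
            prod = 1.0
            for i in range(6):
                state = int(g[i])
                for bit, locus in enumerate(lnd.neighborhoods[i]):
                    state |= int(g[locus]) << (bit + 1)
                prod *= lnd.contributions[i, state]
            assert lnd.fitness(tuple(int(a) for a in g)) == pytest.approx(prod ** (1 / 6))

    def test_fitness_bounded_by_contribution_interval(self, small_nk):
        table = small_nk.fitness_table()
        assert table.min() >= small_nk.c_min and table.max() <= small_nk.c_max

    def test_k0_landscape_is_multiplicative(self, smooth_nk):
        eps = rw.all_quadruple_epsilons(smooth_nk, "multiplicative")
        assert np.abs(eps).max() < 1e-9


class TestRMF:
    def test_rescaled_range_is_exact(self, rmf):
        table = rmf.fitness_table()
        assert table.min() == rmf.w_min and table.max() == rmf.w_max

    def test_zero_noise_is_additive_and_single_peaked(self, rng):
        lnd = rw.make_rmf_landscape(8, slope=0.3, noise_low=0.0, noise_high=0.0, rng=rng)
        table = lnd.fitness_table()
        d = enumerate_genotypes(8).sum(axis=1)
        # fitness strictly increasing in derived-allele count; peak = all-derived
        means = [table[d == k].mean() for k in range(9)]
        assert np.all(np.diff(means) > 0)
        assert np.allclose(table[d == 4], table[d == 4][0])
        assert int(table.argmax()) == (1 << 8) - 1
        assert np.abs(rw.all_quadruple_epsilons(lnd, "additive")).max() < 1e-12

    def test_slope_zero_is_pure_noise(self, rng):
        lnd = rw.make_rmf_landscape(12, slope=0.0, rng=rng)
        d = enumerate_genotypes(12).sum(axis=1)
        table = lnd.fitness_table()
        # no systematic fitness gradient in derived-allele count
        assert abs(np.corrcoef(d.astype(float), table)[0, 1]) < 0.1

    def test_degenerate_raw_range_rejected(self, rng):
        with pytest.raises(ValueError):
            rw.make_rmf_landscape(4, slope=0.0, noise_low=0.5, noise_high=0.5, rng=rng)


class TestLogFitnessMoments:
    def test_matches_numerical_quadrature(self):
        a, b = 0.1, 1.0
        mu, sigma = rw.nk_log_fitness_moments(1, a, b)
        mu_num = integrate.quad(lambda u: np.log(u) / (b - a), a, b)[0]
        var_num = integrate.quad(lambda u: np.log(u) ** 2 / (b - a), a, b)[0] - mu_num ** 2
        assert mu == pytest.approx(mu_num, abs=1e-6)
        assert sigma == pytest.approx(np.sqrt(var_num), abs=1e-6)

    def test_sigma_scales_as_inverse_sqrt_l(self):
        _, s1 = rw.nk_log_fitness_moments(1, 0.1, 1.0)
        _, s4 = rw.nk_log_fitness_moments(4, 0.1, 1.0)
        assert s4 == pytest.approx(s1 / 2)

    def test_degenerate_interval_limit(self):
        mu, sigma = rw.nk_log_fitness_moments(1, 1.0 - 1e-9, 1.0)
        assert mu == pytest.approx(0.0, abs=1e-8)
        assert sigma == pytest.approx(0.0, abs=1e-8)


class TestQuartileBounds:
    def test_empirical_median_uses_linear_interpolation(self):
        lnd = RMFLandscape(L=2, slope=0.0, noise_low=0.0, noise_high=1.0,
                           fitness_table_=[1.0, 2.0, 3.0, 4.0], w_min=1.0, w_max=4.0)
        summary = rw.quartile_bounds(lnd, "empirical")
        assert summary.quartile_bounds[1] == pytest.approx(2.5)

    def test_theoretical_bounds_strictly_increasing(self, small_nk):
        q1, q2, q3 = rw.quartile_bounds(small_nk, "theoretical").quartile_bounds
        assert q1 < q2 < q3

    def test_theoretical_mode_rejected_for_rmf(self, rmf):
        with pytest.raises(ValueError):
            rw.quartile_bounds(rmf, "theoretical")

    def test_quartile_intervals_partition_the_line(self, small_nk):
        summary = rw.quartile_bounds(small_nk, "theoretical")
        lo1, hi1 = summary.quartile_interval(1)
        lo4, hi4 = summary.quartile_interval(4)
        assert lo1 == -np.inf and hi4 == np.inf
        assert hi1 == summary.quartile_bounds[0] and lo4 == summary.quartile_bounds[2]


class TestLowFitnessStarts:
    def test_nk_start_is_below_gaussian_threshold(self, small_nk, rng):
        summary = rw.quartile_bounds(small_nk, "theoretical")
        for _ in range(20):
            g = rw.sample_low_fitness_genotype(small_nk, summary, rng)
            assert np.log(small_nk.fitness(g)) < summary.mu_log - 1.5 * summary.sigma_log

    def test_rmf_start_is_in_bottom_tail(self, rmf, rng):
        summary = rw.quartile_bounds(rmf, "empirical")
        threshold = np.quantile(rmf.fitness_table(), LOW_TAIL_MASS)
        for _ in range(20):
            g = rw.sample_low_fitness_genotype(rmf, summary, rng)
            assert rmf.fitness(g) <= threshold

    def test_constant_landscape_has_empty_tail(self, rng):
        lnd = NKLandscape(L=4, K=0, neighborhoods=np.empty((4, 0), dtype=int),
                          contributions=np.full((4, 2), 0.5), c_min=0.1, c_max=1.0)
        summary = rw.quartile_bounds(lnd, "theoretical")
        with pytest.raises(RuntimeError):
            rw.sample_low_fitness_genotype(lnd, summary, rng, max_tries=512)


class TestNeighborCorrelation:
    def test_k0_landscape_is_strongly_correlated(self, smooth_nk, rng):
        r = rw.neighbor_fitness_correlation(smooth_nk, 4000, rng)
        assert r > 0.5

    def test_correlation_decreases_with_k(self):
        # Monte Carlo over 50 landscapes per K at L=10
        means = []
        for K in (0, 2, 5, 9):
            vals = []
            for i in range(50):
                sub = np.random.default_rng(1000 + 100 * K + i)
                lnd = rw.make_nk_landscape(10, K, rng=sub)
                vals.append(rw.neighbor_fitness_correlation(lnd, 400, sub))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_correlation_increases_with_rmf_slope(self):
        means = []
        for slope in (0.05, 0.25, 1.0):
            vals = []
            for i in range(30):
                sub = np.random.default_rng(2000 + int(slope * 100) + i)
                lnd = rw.make_rmf_landscape(10, slope=slope, rng=sub)
                vals.append(rw.neighbor_fitness_correlation(lnd, 400, sub))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_constant_landscape_rejected(self, rng):
        lnd = RMFLandscape(L=3, slope=0.0, noise_low=0.0, noise_high=1.0,
                           fitness_table_=np.ones(8), w_min=1.0, w_max=2.0)
        with pytest.raises(ValueError):
            rw.neighbor_fitness_correlation(lnd, 100, rng)


def test_fitness_table_tsv_round_trips_values(rmf):
    text = rw.landscapes.fitness_table_tsv(rmf)
    lines = text.strip().split("\n")
    assert lines[0] == "genotype\tfitness"
    assert len(lines) == 1 + (1 << rmf.L)
    bits, w = lines[1].split("\t")
    assert float(w) == pytest.approx(rmf.fitness(tuple(int(c) for c in bits)))
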