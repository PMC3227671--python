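"""Sequence-evolution simulator: HKY+gamma substitutions, Lavalette indels,
inversion planting, and end-to-end reproducibility."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from umiscan.diffscan import estimate_rates
from umiscan.evosim import (
    AT_EXCLUSIVE_COMPOSITION,
    HUMAN_CHIMP_COMPOSITION,
    SimConfig,
    SimPair,
    discrete_gamma_rates,
    evolve_pair,
    hky_rate_matrix,
    lavalette_pmf,
    lavalette_sample,
    make_simulation_set,
    plant_inversion,
    sample_gamma_category_rates,
)
from umiscan.invsearch import reverse_complement
from umiscan.pairalign import global_affine_align


class TestHkyRateMatrix:
    def test_equal_frequencies_kappa_one_is_jukes_cantor(self):
        Q = hky_rate_matrix((0.25, 0.25, 0.25, 0.25), tstv=1.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_at_exclusive_only_a_t_exchanges(self):
        Q = hky_rate_matrix(AT_EXCLUSIVE_COMPOSITION, tstv=1.75)
        # internal order A,C,G,T: only A<->T entries may be nonzero
        assert Q[0, 3] > 0 and Q[3, 0] > 0
        assert Q[1].sum() == 0 and Q[2].sum() == 0
        assert Q[0, 1] == Q[0, 2] == Q[3, 1] == Q[3, 2] == 0

    def test_normalized_to_one_substitution_per_unit_time(self):
        for comp in (HUMAN_CHIMP_COMPOSITION, (0.25, 0.25, 0.25, 0.25)):
            Q = hky_rate_matrix(comp, tstv=1.75)
            ga, gt, gc, gg = comp
            pi = np.array([ga, gc, gg, gt])
            assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_stationary_distribution_is_composition(self):
        comp = HUMAN_CHIMP_COMPOSITION
        Q = hky_rate_matrix(comp, tstv=1.75)
        ga, gt, gc, gg = comp
        pi = np.array([ga, gc, gg, gt])
        P = expm(Q * 50.0)  # long branch: rows converge to stationarity
        for row in P:
            assert np.allclose(row, pi, atol=1e-8)


class TestDiscreteGamma:
    def test_single_category_is_flat(self):
        assert discrete_gamma_rates(0.65, 1) == pytest.approx([1.0])

    def test_category_means_average_to_one(self):
        for shape, cats in ((0.65, 5), (0.2, 4), (2.0, 8)):
            rates = discrete_gamma_rates(shape, cats)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(rates) > 0)

    def test_category_means_match_quadrature(self):
        shape, cats = 0.65, 5
        rates = discrete_gamma_rates(shape, cats)
        bounds = np.concatenate(
            [[0.0], gamma_dist.ppf(np.arange(1, cats) / cats, shape, scale=1 / shape), [np.inf]]
        )
        for k in range(cats):
            mean_k, _ = quad(
                lambda x: x * gamma_dist.pdf(x, shape, scale=1 / shape),
                bounds[k],
                bounds[k + 1],
            )
            assert rates[k] == pytest.approx(cats * mean_k, rel=1e-6)

    def test_per_site_sampling_uses_category_means(self, rng):
        rates = set(discrete_gamma_rates(0.65, 5))
        sampled = sample_gamma_category_rates(0.65, 5, rng, n_sites=500)
        assert set(np.round(sampled, 12)) <= set(np.round(sorted(rates), 12))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(-1.0, 5)


class TestLavalette:
    def test_max_len_one_always_one(self, rng):
        assert lavalette_pmf(2.0, 1) == pytest.approx([1.0])
        assert np.all(lavalette_sample(2.0, 1, rng, size=100) == 1)

    def test_mode_at_one(self):
        pmf = lavalette_pmf(2.0, 50)
        assert pmf[0] == pmf.max()
        assert np.all(np.diff(pmf) < 0)

    def test_empirical_frequencies_match_pmf(self, rng):
        pmf = lavalette_pmf(2.0, 50)
        n = 300_000
        draws = lavalette_sample(2.0, 50, rng, size=n)
        counts = np.bincount(draws, minlength=51)[1:]
        for l in (1, 2, 5, 10, 50):
            p = pmf[l - 1]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[l - 1] / n - p) < 3 * se + 1e-6


class TestEvolvePair:
    def test_zero_rates_copies_root(self, rng):
        cfg = SimConfig(root_length=400, subs_per_site=0.0, indel_sub_ratio=0.0)
        sim = evolve_pair(cfg, rng)
        assert sim.seq_a == sim.seq_b
        assert len(sim.seq_a) == 400

    def test_base_composition_preserved(self, rng):
        cfg = SimConfig(root_length=200_000, subs_per_site=0.02)
        sim = evolve_pair(cfg, rng)
        ga, gt, gc, gg = cfg.base_comp
        for seq in (sim.seq_a, sim.seq_b):
            n = len(seq)
            assert seq.count("A") / n == pytest.approx(ga, abs=0.01)
            assert seq.count("T") / n == pytest.approx(gt, abs=0.01)
            assert seq.count("C") / n == pytest.approx(gc, abs=0.01)

    def test_realized_difference_density_matches_calibration(self, rng):
        # the default divergence is calibrated so that the re-aligned pairs
        # show ~0.0100 mismatches+gap blocks and ~0.0015 gap blocks per column
        cfg = SimConfig(root_length=2000)
        pairs = []
        for _ in range(50):
            sim = evolve_pair(cfg, rng)
            pairs.append(global_affine_align(sim.seq_a, sim.seq_b))
        rates = estimate_rates(pairs)
        assert rates.p_d == pytest.approx(0.0100, rel=0.10)
        assert rates.p_g == pytest.approx(0.0015, rel=0.25)

    def test_indel_substitution_ratio(self, rng):
        # count realized indel events against substitutions on ungapped copies
        cfg = SimConfig(root_length=50_000, subs_per_site=0.02)
        pairs = []
        for _ in range(4):
            sim = evolve_pair(cfg, rng)
            pairs.append(global_affine_align(sim.seq_a, sim.seq_b))
        rates = estimate_rates(pairs)
        ratio = rates.p_g / (rates.p_d - rates.p_g)
        assert ratio == pytest.approx(cfg.indel_sub_ratio, rel=0.30)


class TestPlantInversion:
    def test_involution_and_truth(self, rng):
        cfg = SimConfig(root_length=500)
        sim = evolve_pair(cfg, rng)
        planted = plant_inversion(sim, 20, rng)
        s, e = planted.truth_start, planted.truth_end
        assert e - s == 20 == planted.inversion_length
        restored = (
            planted.seq_b[:s]
            + reverse_complement(planted.seq_b[s:e])
            + planted.seq_b[e:]
        )
        assert restored == sim.seq_b

    def test_placement_roughly_uniform(self, rng):
        length = 10
        seq = "A" * 1000
        sim = SimPair("A" * 1000, seq)
        starts = [plant_inversion(sim, length, rng).truth_start for _ in range(4000)]
        counts, _ = np.histogram(starts, bins=10, range=(0, 1000 - length + 1))
        expected = len(starts) / 10
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 27.9  # chi-square_{9, 0.999}

    def test_too_long_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_inversion(SimPair("ACGT", "ACGT"), 10, rng)


class TestMakeSimulationSet:
    def test_seeded_determinism_and_truth(self):
        cfg = SimConfig(root_length=600, inversion_length=10, n_pairs=4, seed=99)
        first = list(make_simulation_set(cfg))
        second = list(make_simulation_set(cfg))
        assert len(first) == cfg.n_pairs
        for (s1, p1), (s2, p2) in zip(first, second):
            assert s1.seq_a == s2.seq_a and s1.seq_b == s2.seq_b
            assert (s1.truth_start, s1.truth_end) == (s2.truth_start, s2.truth_end)
            assert p1.text_a == p2.text_a and p1.text_b == p2.text_b
            # exactly one planted inversion, recorded consistently
            assert s1.truth_end - s1.truth_start == 10
            assert p1.ungapped("b") == s1.seq_b
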