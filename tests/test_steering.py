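import numpy as np
import pytest
from scipy.stats import ks_2samp

from steerkit.geometry import NoiseSchedule
from steerkit.potentials import PotentialWeights, total_energy
from steerkit.steering import (
    GaussianAncestralSampler, Particle, SteeringConfig, fk_steer,
    importance_weights, resample,
)
from steerkit.synthetic import (
    ChainSpec, ToySpec, inject_violation, make_denoiser, make_toy_complex,
)
from conftest import VIOLATION_FIXTURES


class TestImportanceWeights:
    def test_uniform_when_everything_equal(self):
        w = importance_weights(np.zeros(4), np.zeros(4), np.zeros(4),
                               np.zeros(4), lambda_=2.0)
        np.testing.assert_allclose(w, 0.25)

    def test_energy_difference_closed_form(self):
        """ΔE = (0, 1/λ) gives weights (e, 1)/(e+1)."""
        lam = 2.0
        w = importance_weights(np.array([0.0, 1.0 / lam]), np.zeros(2),
                               np.zeros(2), np.zeros(2), lam)
        np.testing.assert_allclose(w, [np.e / (np.e + 1), 1 / (np.e + 1)])

    def test_ratio_term_cancels_without_guidance(self):
        """Identical guided/unguided densities leave only the energy term."""
        dens = np.array([-12.3, -45.6, -7.8])
        w = importance_weights(np.ones(3), np.ones(3), dens, dens, 1.0)
        np.testing.assert_allclose(w, 1 / 3)

    def test_underflow_falls_back_to_uniform(self):
        w = importance_weights(np.array([1e9, 2e9]), np.zeros(2),
                               np.zeros(2), np.array([-np.inf, -np.inf]), 1.0)
        np.testing.assert_allclose(w, 0.5)


class TestResample:
    def _particles(self, k):
        return [Particle(x_t=np.full((3, 3), float(i)),
                         delta=np.ones((3, 3))) for i in range(k)]

    def test_certain_weight_copies_one_particle(self):
        out = resample(self._particles(3), np.array([0.0, 1.0, 0.0]),
                       np.random.default_rng(0))
        for p in out:
            np.testing.assert_allclose(p.x_t, 1.0)
            np.testing.assert_allclose(p.delta, 0.0)  # offsets reset

    def test_uniform_weights_uniform_frequencies(self):
        rng = np.random.default_rng(1)
        k = 5
        counts = np.zeros(k)
        draws = 20_000  # k draws each -> 100k selections
        particles = self._particles(k)
        w = np.full(k, 1 / k)
        for _ in range(draws):
            for p in resample(particles, w, rng):
                counts[int(p.x_t[0, 0])] += 1
        total = draws * k
        p_exp = 1 / k
        sigma = np.sqrt(p_exp * (1 - p_exp) * total)
        assert np.all(np.abs(counts - total * p_exp) < 4 * sigma)

    def test_expected_copies_match_weights(self):
        """Weights (0.9, 0.1), k=2: particle 1 expects 1.8 copies."""
        rng = np.random.default_rng(2)
        particles = self._particles(2)
        w = np.array([0.9, 0.1])
        copies = [sum(int(p.x_t[0, 0]) == 0 for p in resample(particles, w, rng))
                  for _ in range(20_000)]
        assert np.mean(copies) == pytest.approx(1.8, abs=0.02)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            resample(self._particles(2), np.array([1.2, -0.2]),
                     np.random.default_rng(0))


class TestSamplerContract:
    def test_logpdf_consistent_with_sampling(self):
        """Empirical mean log-density of samples matches the Gaussian
        entropy prediction."""
        rng = np.random.default_rng(3)
        sampler = GaussianAncestralSampler(align=False)
        x_t = rng.standard_normal((5, 3)) * 3
        x_hat = rng.standard_normal((5, 3))
        sigma_t, sigma_next = 3.0, 1.5
        n = x_t.size
        _, std = sampler._moments(x_hat, x_t, sigma_t, sigma_next)
        expected = -0.5 * n * (1 + np.log(2 * np.pi * std ** 2))
        vals = [sampler.logpdf(sampler.sample(x_hat, x_t, sigma_t, sigma_next, rng),
                               x_hat, x_t, sigma_t, sigma_next)
                for _ in range(3000)]
        assert np.mean(vals) == pytest.approx(expected, rel=0.03)


@pytest.fixture(scope="module")
def overlap_system():
    complex_, cs, _ = make_toy_complex(ToySpec(
        chains=[ChainSpec("nonpolymer", template="ring", copies=2)]))
    bad = inject_violation(complex_, cs, "chain_overlap", magnitude=0.5)
    return bad.coords_matrix, cs


class TestFkSteer:
    def test_unsteered_limit_matches_plain_sampler(self):
        """λ=0, m=0 steering is distributionally identical to the plain
        sampler (two-sample KS on a coordinate functional, n=2000)."""
        complex_, cs, _ = make_toy_complex(ToySpec(chains=[ChainSpec("protein", 5)]))
        target = complex_.coords_matrix - complex_.coords_matrix.mean(0)

        def shrink_denoiser(x, sigma):
            w = 1.0 / (1.0 + sigma ** 2)
            return target + w * (x - target)

        sched = NoiseSchedule(num_steps=6, sigma_min=0.1, sigma_max=5.0)
        sampler = GaussianAncestralSampler(align=False)
        cfg_multi = SteeringConfig(num_particles=4, guidance_steps=0,
                                   weights=PotentialWeights(lambda_=0.0))
        cfg_single = SteeringConfig(num_particles=1, guidance_steps=0,
                                    weights=PotentialWeights(lambda_=0.0))
        a = [fk_steer(shrink_denoiser, sampler, cs, sched, cfg_multi,
                      len(target), s)[0][0, 0] for s in range(2000)]
        b = [fk_steer(shrink_denoiser, sampler, cs, sched, cfg_single,
                      len(target), 10_000 + s)[0][0, 0] for s in range(2000)]
        assert ks_2samp(a, b).pvalue > 0.01

    def test_lambda_zero_weights_uniform(self, overlap_system):
        target, cs = overlap_system
        sched = NoiseSchedule(num_steps=9, sigma_min=0.1, sigma_max=5.0)
        cfg = SteeringConfig(num_particles=4, guidance_steps=0,
                             weights=PotentialWeights(lambda_=0.0))
        _, diag = fk_steer(make_denoiser("ideal", target),
                           GaussianAncestralSampler(), cs, sched, cfg,
                           len(target), 0)
        for w in diag["weights"]:
            np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_resampling_events_every_third_step(self, overlap_system):
        target, cs = overlap_system
        sched = NoiseSchedule(num_steps=30, sigma_min=0.1, sigma_max=5.0)
        cfg = SteeringConfig(num_particles=2, resample_interval=3,
                             guidance_steps=0, weights=PotentialWeights())
        _, diag = fk_steer(make_denoiser("ideal", target),
                           GaussianAncestralSampler(), cs, sched, cfg,
                           len(target), 1)
        assert diag["resample_steps"] == list(range(0, 30, 3))

    def test_steering_separates_coincident_chains(self, overlap_system):
        """Ideal denoiser pinned on overlapping symmetric chains: steering
        pushes the centroids beyond the schedule's minimum in ≥95% of seeds
        while the unsteered sampler essentially never does."""
        target, cs = overlap_system
        ia, ib = cs.symmetric_chain_pairs[0]
        sched = NoiseSchedule(num_steps=21, sigma_min=0.05, sigma_max=10.0)
        sampler = GaussianAncestralSampler()
        den = make_denoiser("ideal", target)
        cfg_s = SteeringConfig(num_particles=4, guidance_steps=20,
                               guidance_step_size=1.0,
                               weights=PotentialWeights())
        cfg_p = SteeringConfig(num_particles=1, guidance_steps=0,
                               weights=PotentialWeights(lambda_=0.0))
        b_min = 1.0  # smallest centroid separation the schedule demands
        n_seeds = 60
        fixed = fixed_plain = 0
        for seed in range(n_seeds):
            xs, _ = fk_steer(den, sampler, cs, sched, cfg_s, len(target), seed)
            xp, _ = fk_steer(den, sampler, cs, sched, cfg_p, len(target), seed)
            fixed += np.linalg.norm(xs[ia].mean(0) - xs[ib].mean(0)) >= b_min
            fixed_plain += np.linalg.norm(xp[ia].mean(0) - xp[ib].mean(0)) >= b_min
        assert fixed >= 0.95 * n_seeds
        assert fixed_plain < 0.5 * n_seeds

    @pytest.mark.parametrize("kind", sorted(VIOLATION_FIXTURES))
    def test_steered_energy_stochastically_below_unsteered(self, kind):
        """On every injected-violation fixture, the steered output's energy
        is (paired over seeds) at most the unsteered sampler's."""
        chains, extra = VIOLATION_FIXTURES[kind]
        complex_, cs, _ = make_toy_complex(ToySpec(chains=chains, **extra))
        bad = inject_violation(complex_, cs, kind)
        target = bad.coords_matrix
        den = make_denoiser("ideal", target)
        sched = NoiseSchedule(num_steps=15, sigma_min=0.05, sigma_max=10.0)
        sampler = GaussianAncestralSampler()
        w = PotentialWeights()
        cfg_s = SteeringConfig(num_particles=4, guidance_steps=20,
                               guidance_step_size=1.0, weights=w)
        cfg_p = SteeringConfig(num_particles=1, guidance_steps=0,
                               weights=PotentialWeights(lambda_=0.0))
        wins = 0
        e_s, e_p = [], []
        n_seeds = 12
        for seed in range(n_seeds):
            xs, _ = fk_steer(den, sampler, cs, sched, cfg_s, len(target), seed)
            xp, _ = fk_steer(den, sampler, cs, sched, cfg_p, len(target), seed)
            a = total_energy(xs, cs, w, 0.0)
            b = total_energy(xp, cs, w, 0.0)
            e_s.append(a)
            e_p.append(b)
            wins += a <= b + 1e-9
        assert wins >= 0.9 * n_seeds
        assert np.mean(e_s) < np.mean(e_p)

    def test_seed_determinism(self, overlap_system):
        target, cs = overlap_system
        sched = NoiseSchedule(num_steps=9, sigma_min=0.1, sigma_max=5.0)
        cfg = SteeringConfig(num_particles=3, weights=PotentialWeights())
        den = make_denoiser("ideal", target)
        x1, d1 = fk_steer(den, GaussianAncestralSampler(), cs, sched, cfg,
                          len(target), 42)
        x2, d2 = fk_steer(den, GaussianAncestralSampler(), cs, sched, cfg,
                          len(target), 42)
        np.testing.assert_array_equal(x1, x2)
        assert d1["weights"] == d2["weights"]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SteeringConfig(num_particles=0)
        with pytest.raises(ValueError):
            SteeringConfig(resample_interval=0)
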