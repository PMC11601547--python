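"""Feynman–Kac steering of a reverse-diffusion sampler.

A pluggable denoiser ``f(x, σ) → x̂`` and a Gaussian transition kernel are
wrapped in a sequential-Monte-Carlo loop: k particles are propagated
through the reverse trajectory, gradient-descent offsets on the constraint
potential tilt each kernel toward low-energy denoised predictions
(backwards universal guidance), and every ``resample_interval`` steps the
particles are multinomially resampled under importance weights built from
the energy change since the last checkpoint, corrected by the
guided/unguided proposal-density ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .geometry import NoiseSchedule, apply_rigid, kabsch_align
from .potentials import ConstraintSet, PotentialWeights, grad_total_energy, total_energy

logger = logging.getLogger(__name__)


class GaussianAncestralSampler:
    """Ancestral Gaussian transition kernel for variance-exploding diffusion.

    The mean interpolates the current state toward the (optionally
    Kabsch-aligned) denoised prediction, ``μ = x̂ + (σ_next/σ_t)(x_t − x̂)``,
    with isotropic noise of standard deviation ``σ_next·sqrt(1 − (σ_next/σ_t)²)``.
    Sampling and log-density share the same mean computation, so the
    density-ratio correction of guided proposals is exact.
    """

    def __init__(self, align: bool = True, noise_scale: float = 1.0):
        self.align = align
        self.noise_scale = noise_scale

    def _moments(self, x_hat: np.ndarray, x_t: np.ndarray,
                 sigma_t: float, sigma_next: float) -> tuple[np.ndarray, float]:
        if self.align:
            try:
                R, t, _ = kabsch_align(x_hat, x_t)
                x_hat = apply_rigid(x_hat, R, t)
            except ValueError:
                pass  # degenerate prediction: no frame to align
        r = sigma_next / sigma_t
        mean = x_hat + r * (x_t - x_hat)
        std = self.noise_scale * sigma_next * np.sqrt(max(1.0 - r * r, 0.0))
        return mean, std

    def sample(self, x_hat: np.ndarray, x_t: np.ndarray, sigma_t: float,
               sigma_next: float, rng: np.random.Generator) -> np.ndarray:
        mean, std = self._moments(x_hat, x_t, sigma_t, sigma_next)
        return mean + std * rng.standard_normal(x_t.shape)

    def logpdf(self, x_next: np.ndarray, x_hat: np.ndarray, x_t: np.ndarray,
               sigma_t: float, sigma_next: float) -> float:
        mean, std = self._moments(x_hat, x_t, sigma_t, sigma_next)
        if std <= 0:
            return 0.0 if np.allclose(x_next, mean) else -np.inf
        n = x_next.size
        sq = float(np.sum((x_next - mean) ** 2))
        return -0.5 * (sq / std ** 2 + n * np.log(2.0 * np.pi * std ** 2))


@dataclass
class Particle:
    """One SMC particle: state, latest denoised prediction, guidance offset,
    and bookkeeping for the telescoping energy weights."""

    x_t: np.ndarray
    x_hat: np.ndarray | None = None
    delta: np.ndarray | None = None
    log_weight: float = 0.0
    energy_prev: float = 0.0

    def copy(self) -> "Particle":
        return Particle(
            x_t=self.x_t.copy(),
            x_hat=None if self.x_hat is None else self.x_hat.copy(),
            delta=None if self.delta is None else self.delta.copy(),
            log_weight=self.log_weight,
            energy_prev=self.energy_prev,
        )


@dataclass
class SteeringConfig:
    num_particles: int = 4
    resample_interval: int = 3
    guidance_steps: int = 4
    guidance_step_size: float = 0.2
    max_guidance_displacement: float = 0.5  # Å per gradient step, per atom
    weights: PotentialWeights = field(default_factory=PotentialWeights)

    def __post_init__(self) -> None:
        if self.num_particles < 1:
            raise ValueError("need at least one particle")
        if self.resample_interval < 1:
            raise ValueError("resample_interval must be ≥ 1")
        if self.guidance_steps < 0:
            raise ValueError("guidance_steps must be ≥ 0")


def importance_weights(energies_now: np.ndarray, energies_prev: np.ndarray,
                       guided_logdensity: np.ndarray,
                       unguided_logdensity: np.ndarray,
                       lambda_: float) -> np.ndarray:
    """Normalized FK importance weights.

    ``w ∝ exp(logτ_unguided − logτ_guided) · exp(λ(E_prev − E_now))``,
    computed in log space; an all-underflow ensemble falls back to uniform
    weights with a warning.
    """
    log_w = (np.asarray(unguided_logdensity, dtype=float)
             - np.asarray(guided_logdensity, dtype=float)
             + lambda_ * (np.asarray(energies_prev, dtype=float)
                          - np.asarray(energies_now, dtype=float)))
    if not np.any(np.isfinite(log_w)):
        logger.warning("importance weights underflowed; falling back to uniform")
        return np.full(len(log_w), 1.0 / len(log_w))
    log_w = log_w - logsumexp(log_w)
    w = np.exp(log_w)
    return w / w.sum()


def resample(particles: list[Particle], weights: np.ndarray,
             rng: np.random.Generator) -> list[Particle]:
    """Multinomial resampling with replacement; surviving copies get uniform
    log-weights and zeroed guidance offsets."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative importance weight")
    weights = weights / weights.sum()
    k = len(particles)
    idx = rng.choice(k, size=k, p=weights)
    out = []
    for i in idx:
        p = particles[i].copy()
        p.log_weight = -np.log(k)
        if p.delta is not None:
            p.delta = np.zeros_like(p.delta)
        out.append(p)
    return out


def _guidance_offsets(particle: Particle, constraints: ConstraintSet,
                      config: SteeringConfig, t_norm: float) -> np.ndarray:
    """m gradient-descent steps on E(x̂ + Δ), with per-step displacement
    capped so guidance cannot blow up a near-feasible structure."""
    delta = np.zeros_like(particle.x_hat)
    for _ in range(config.guidance_steps):
        g = grad_total_energy(particle.x_hat + delta, constraints,
                              config.weights, t_norm)
        step = config.guidance_step_size * g
        max_disp = float(np.max(np.linalg.norm(step, axis=1))) if step.size else 0.0
        if max_disp > config.max_guidance_displacement:
            step *= config.max_guidance_displacement / max_disp
        delta -= step
    return delta


def fk_steer(denoiser, sampler: GaussianAncestralSampler,
             constraints: ConstraintSet, schedule: NoiseSchedule,
             config: SteeringConfig, n_atoms: int, seed: int
             ) -> tuple[np.ndarray, dict]:
    """Run the steered reverse diffusion and return the first particle's
    final guided prediction plus trajectory diagnostics.

    Checkpoints fall at every ``resample_interval``-th step counted from the
    start (the first step included, where the weight is ``exp(−λE)``).
    Between checkpoints the guidance offset persists and biases every
    transition kernel; weights at a checkpoint compare the energy against
    the previous checkpoint so per-step factors telescope.
    """
    rng = np.random.default_rng(seed)
    sigmas = schedule.sigmas()
    T = schedule.num_steps
    lam = config.weights.lambda_
    particles = [Particle(x_t=sigmas[0] * rng.standard_normal((n_atoms, 3)))
                 for _ in range(config.num_particles)]
    prev: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
    diagnostics = {"resample_steps": [], "weights": [], "mean_energy": [],
                   "sigmas": sigmas.tolist()}

    for i in range(T):
        sigma_t = sigmas[i]
        t_norm = schedule.normalized_time(sigma_t)
        if i > 0:
            assert prev is not None
            for p, (x_prev, xhat_prev, delta_prev) in zip(particles, prev):
                p.x_t = sampler.sample(xhat_prev + delta_prev, x_prev,
                                       sigmas[i - 1], sigma_t, rng)
        for p in particles:
            p.x_hat = denoiser(p.x_t, sigma_t)
            if not np.all(np.isfinite(p.x_hat)) or not np.all(np.isfinite(p.x_t)):
                raise RuntimeError(f"non-finite coordinates at step {i}")
            if p.delta is None:
                p.delta = np.zeros_like(p.x_hat)

        if i % config.resample_interval == 0:
            e_now = np.array([total_energy(p.x_hat, constraints,
                                           config.weights, t_norm)
                              for p in particles])
            if not np.all(np.isfinite(e_now)):
                raise RuntimeError(f"non-finite energy at step {i}")
            if i == 0:
                log_guided = np.zeros(len(particles))
                log_unguided = np.zeros(len(particles))
                e_prev = np.zeros(len(particles))
            else:
                assert prev is not None
                log_guided = np.array([
                    sampler.logpdf(p.x_t, xh + d, xp, sigmas[i - 1], sigma_t)
                    for p, (xp, xh, d) in zip(particles, prev)])
                log_unguided = np.array([
                    sampler.logpdf(p.x_t, xh, xp, sigmas[i - 1], sigma_t)
                    for p, (xp, xh, d) in zip(particles, prev)])
                e_prev = np.array([p.energy_prev for p in particles])
            w = importance_weights(e_now, e_prev, log_guided, log_unguided, lam)
            for p, e in zip(particles, e_now):
                p.energy_prev = float(e)
            particles = resample(particles, w, rng)
            for p in particles:
                p.delta = _guidance_offsets(p, constraints, config, t_norm)
            diagnostics["resample_steps"].append(i)
            diagnostics["weights"].append(w.tolist())
        diagnostics["mean_energy"].append(float(np.mean([
            total_energy(p.x_hat, constraints, config.weights, t_norm)
            for p in particles])))
        prev = [(p.x_t.copy(), p.x_hat.copy(), p.delta.copy()) for p in particles]

    final = particles[0].x_hat + particles[0].delta
    return final, diagnostics
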