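"""Gradient-based MCMC: Hamiltonian Monte Carlo with warmup adaptation.

A self-contained HMC implementation for smooth, unconstrained log densities
supplied as a ``logp_and_grad(x) -> (float, ndarray)`` callable.  Warmup
follows the usual windowed scheme: dual-averaging step-size adaptation toward
a target acceptance statistic throughout, with a diagonal mass matrix
re-estimated from an intermediate warmup window.  Sampling uses jittered
trajectory lengths (a uniformly drawn number of leapfrog steps up to the
adapted maximum) to avoid resonance pathologies of fixed-length HMC.

Divergences (large energy errors) are rejected and counted; they are reported
in the per-chain stats so callers can flag unreliable fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["hmc_chain", "ChainStats"]


@dataclass
class ChainStats:
    """Per-chain adaptation and acceptance diagnostics."""

    accept_rate: float
    step_size: float
    n_divergent: int
    max_leapfrog: int


def _energy(lp: float, p: np.ndarray, inv_mass: np.ndarray) -> float:
    if not np.isfinite(lp):
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        kinetic = 0.5 * float(np.sum(inv_mass * p**2))
    return lp - kinetic if np.isfinite(kinetic) else -np.inf


def _leapfrog(logp_and_grad, x, p, grad, eps, n_steps, inv_mass):
    """Standard leapfrog integration; returns proposal state and final grad."""
    x = x.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * grad
        for i in range(n_steps):
            x = x + eps * inv_mass * p
            if not np.all(np.isfinite(x)):
                return x, p, -np.inf, grad
            lp, grad = logp_and_grad(x)
            if not np.isfinite(lp):
                return x, p, lp, grad
            p = p + eps * grad * (0.5 if i == n_steps - 1 else 1.0)
    return x, p, lp, grad


def _find_initial_step(logp_and_grad, x0, inv_mass, rng):
    """Heuristic doubling/halving search for a step size with ~50% acceptance."""
    eps = 1.0
    lp0, grad0 = logp_and_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = _energy(lp0, p0, inv_mass)
    x1, p1, lp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, 1, inv_mass)
    h1 = _energy(lp1, p1, inv_mass)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, lp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, 1, inv_mass)
        h1 = _energy(lp1, p1, inv_mass)
        crossed = (h1 - h0) > np.log(0.5)
        if (direction == 1.0 and not crossed) or (direction == -1.0 and crossed):
            break
    return min(eps, 2.0)


def hmc_chain(
    logp_and_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    trajectory_length: float = 1.0,
    max_leapfrog: int = 128,
    divergence_threshold: float = 1000.0,
) -> tuple[np.ndarray, ChainStats]:
    """Run one HMC chain; returns (samples [n_samples, dim], stats).

    ``trajectory_length`` is the nominal integration time eps * L in the
    mass-standardized geometry; the realized number of leapfrog steps per
    iteration is drawn uniformly from [1, L] to decorrelate trajectories.
    """
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_and_grad, x, inv_mass, rng)

    # Dual averaging state (Hoffman & Gelman 2014 defaults).
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # Warmup windows: step size only / mass estimation / step size re-tune.
    w1 = max(1, int(0.15 * n_warmup))
    w2 = max(1, int(0.75 * n_warmup))
    mass_buf: list[np.ndarray] = []

    lp, grad = logp_and_grad(x)
    samples = np.empty((n_samples, dim))
    n_acc = 0
    n_div = 0
    da_iter = 0

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = _energy(lp, p0, inv_mass)
        L_max = int(np.clip(np.round(trajectory_length / eps), 1, max_leapfrog))
        L = int(rng.integers(max(1, L_max // 2), L_max + 1))
        x1, p1, lp1, grad1 = _leapfrog(logp_and_grad, x, p0, grad, eps, L, inv_mass)
        h1 = _energy(lp1, p1, inv_mass)
        delta_h = h1 - h0 if np.isfinite(h1) else -np.inf
        divergent = not np.isfinite(delta_h) or (h0 - h1) > divergence_threshold
        alpha = 0.0 if divergent else min(1.0, np.exp(min(0.0, delta_h)))
        if (not divergent) and rng.random() < alpha:
            x, lp, grad = x1, lp1, grad1
            if not warming:
                n_acc += 1
        if divergent and not warming:
            n_div += 1

        if warming:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - alpha) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w1 <= it < w2:
                mass_buf.append(x.copy())
            if it == w2 - 1 and len(mass_buf) >= 10:
                var = np.var(np.asarray(mass_buf), axis=0)
                # Regularize toward unity as Stan does for short windows.
                n = len(mass_buf)
                inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3 * np.ones(dim) + 1e-10
                inv_mass = np.maximum(inv_mass, 1e-8)
                eps = float(np.exp(log_eps_bar))
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if da_iter > 0 else eps
        else:
            samples[it - n_warmup] = x

    stats = ChainStats(
        accept_rate=n_acc / max(1, n_samples),
        step_size=eps,
        n_divergent=n_div,
        max_leapfrog=max_leapfrog,
    )
    return samples, stats
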