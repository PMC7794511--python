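"""A small adaptive Hamiltonian Monte Carlo sampler.

Plain leapfrog HMC with dual-averaging step-size adaptation toward a target
acceptance rate, diagonal mass-matrix estimation during warmup, and a
jittered number of leapfrog steps per iteration. Written for posteriors
whose gradient is available analytically (the mortality model supplies
one); dimensions into the low thousands are fine on one core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HmcResult", "hmc_sample"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HmcResult:
    draws: np.ndarray          # (n_draws, dim), post-warmup
    accept_rate: float
    step_size: float
    n_divergent: int


def _find_initial_step(logp_grad: LogpGrad, theta: np.ndarray, inv_mass: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Double/halve the step until one leapfrog step has accept prob near 0.5."""
    eps = 0.1
    lp0, g0 = logp_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * float(r @ (inv_mass * r))

    def one_step(eps: float) -> float:
        r1 = r + 0.5 * eps * g0
        t1 = theta + eps * inv_mass * r1
        lp1, g1 = logp_grad(t1)
        r1 = r1 + 0.5 * eps * g1
        return lp1 - 0.5 * float(r1 @ (inv_mass * r1)) - h0

    dh = one_step(eps)
    if not np.isfinite(dh):
        dh = -np.inf
    direction = 1 if dh > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        dh = one_step(eps)
        if not np.isfinite(dh):
            dh = -np.inf
        if (direction == 1 and dh <= np.log(0.5)) or (direction == -1 and dh >= np.log(0.5)):
            break
    return eps


def hmc_sample(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
) -> HmcResult:
    """Run one HMC chain; returns post-warmup draws.

    The number of leapfrog steps per iteration is drawn uniformly from
    ``[max_leapfrog // 2, max_leapfrog]`` to decorrelate trajectory lengths.
    Diagonal mass is re-estimated twice during warmup (at 40% and 75%) from
    the preceding window of warmup draws.
    """
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    lp, grad = logp_grad(theta)
    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_divergent = 0
    mass_updates = {int(0.4 * n_warmup), int(0.75 * n_warmup)}
    window: list[np.ndarray] = []

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        n_leap = int(rng.integers(max_leapfrog // 2, max_leapfrog + 1))
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * float(r0 @ (inv_mass * r0))

        t_prop, r_prop, g_prop = theta.copy(), r0.copy(), grad
        lp_prop = lp
        diverged = False
        for _ in range(n_leap):
            r_prop = r_prop + 0.5 * eps * g_prop
            t_prop = t_prop + eps * inv_mass * r_prop
            lp_prop, g_prop = logp_grad(t_prop)
            if not np.isfinite(lp_prop):
                diverged = True
                break
            r_prop = r_prop + 0.5 * eps * g_prop

        if diverged:
            alpha = 0.0
            n_divergent += int(not warming)
        else:
            h1 = lp_prop - 0.5 * float(r_prop @ (inv_mass * r_prop))
            dh = h1 - h0
            if dh < -1000.0:  # energy blow-up
                alpha = 0.0
                n_divergent += int(not warming)
            else:
                alpha = min(1.0, float(np.exp(min(dh, 0.0))))
        if rng.random() < alpha:
            theta, lp, grad = t_prop, lp_prop, g_prop
            n_accept += int(not warming)

        if warming:
            # dual averaging
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            window.append(theta.copy())
            if it in mass_updates and len(window) >= 20:
                var = np.var(np.asarray(window[len(window) // 2:]), axis=0)
                inv_mass = np.clip(var, 1e-8, None)
                window = []
                eps = float(np.exp(log_eps_bar))  # restart from averaged step
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta

    return HmcResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        n_divergent=n_divergent,
    )
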