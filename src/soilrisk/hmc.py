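"""Adaptive Hamiltonian Monte Carlo with analytic gradients.

A compact HMC engine used by all Bayesian models in the package: dual
averaging of the step size toward a target acceptance rate, diagonal mass
matrix adapted from warmup draws, and jittered trajectory lengths.  The
models supply a ``logp_and_grad(theta)`` callable; chains are fully
reproducible given a seed.  Convergence diagnostics (split R-hat and
effective sample size) are computed with arviz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class McmcConfig:
    """Sampler settings.

    ``n_warmup``/``n_draws`` are per chain; 2 chains are run by default so
    that split-R-hat is meaningful.  ``trajectory_length`` is in mass-scaled
    parameter units; the number of leapfrog steps per transition is
    trajectory_length / step_size with +/-50% jitter, capped at
    ``max_leapfrog``.
    """

    n_warmup: int = 400
    n_draws: int = 400
    n_chains: int = 2
    target_accept: float = 0.8
    trajectory_length: float = 1.2
    max_leapfrog: int = 48
    init_step: float = 0.1


@dataclass
class McmcResult:
    draws: np.ndarray  # (n_chains, n_draws, dim)
    accept_rate: float
    step_size: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def sample_hmc(logp_and_grad, theta0: np.ndarray, config: McmcConfig, seed) -> McmcResult:
    """Run ``config.n_chains`` HMC chains from jittered starts."""
    theta0 = np.asarray(theta0, dtype=float)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.n_chains)
    all_draws = []
    acc, step = [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        start = theta0 + 0.01 * rng.standard_normal(theta0.shape)
        draws, a, s = _one_chain(logp_and_grad, start, config, rng)
        all_draws.append(draws)
        acc.append(a)
        step.append(s)
    return McmcResult(np.stack(all_draws), float(np.mean(acc)), float(np.mean(step)))


def _one_chain(logp_and_grad, theta: np.ndarray, cfg: McmcConfig, rng: np.random.Generator):
    dim = theta.size
    inv_mass = np.ones(dim)
    step = cfg.init_step
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("log posterior not finite at the initial point")

    # dual-averaging state (Nesterov primal averaging, standard constants)
    gamma, t0, kappa_da = 0.05, 10.0, 0.75
    mu = np.log(10.0 * step)
    log_step_bar, h_bar, da_m = np.log(step), 0.0, 0

    n_total = cfg.n_warmup + cfg.n_draws
    draws = np.empty((cfg.n_draws, dim))
    # warmup phases: step adapt | + variance collection | step re-adapt
    var_lo = max(int(0.15 * cfg.n_warmup), 1)
    var_hi = max(int(0.75 * cfg.n_warmup), var_lo + 1)
    welford_n, welford_m, welford_s = 0, np.zeros(dim), np.zeros(dim)
    n_accept = 0.0

    for it in range(n_total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_leap = max(1, min(cfg.max_leapfrog, int(cfg.trajectory_length / step * rng.uniform(0.5, 1.5))))
        th, g, lp = theta.copy(), grad.copy(), logp
        p = p0 + 0.5 * step * g
        diverged = False
        for leap in range(n_leap):
            th = th + step * inv_mass * p
            lp, g = logp_and_grad(th)
            if not np.isfinite(lp):
                diverged = True
                break
            p = p + (step if leap < n_leap - 1 else 0.5 * step) * g
        if diverged:
            accept_prob = 0.0
        else:
            h0 = -logp + 0.5 * np.sum(inv_mass * p0 * p0)
            h1 = -lp + 0.5 * np.sum(inv_mass * p * p)
            accept_prob = min(1.0, np.exp(min(h0 - h1, 0.0)))
            if rng.uniform() < accept_prob:
                theta, logp, grad = th, lp, g
        if it >= cfg.n_warmup:
            n_accept += accept_prob
            draws[it - cfg.n_warmup] = theta
        else:
            # dual averaging
            da_m += 1
            h_bar = (1 - 1 / (da_m + t0)) * h_bar + (cfg.target_accept - accept_prob) / (da_m + t0)
            log_step = mu - np.sqrt(da_m) / gamma * h_bar
            eta = da_m ** (-kappa_da)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = float(np.exp(np.clip(log_step, -15.0, 5.0)))
            if var_lo <= it < var_hi:
                welford_n += 1
                d = theta - welford_m
                welford_m += d / welford_n
                welford_s += d * (theta - welford_m)
            if it == var_hi - 1 and welford_n > 10:
                var = welford_s / max(welford_n - 1, 1)
                inv_mass = np.maximum(var, 1e-8)
                # mass changed: restart step-size adaptation from the
                # averaged step so the final phase re-equilibrates
                step = float(np.exp(log_step_bar))
                mu = np.log(10.0 * step)
                h_bar, da_m = 0.0, 0
            if it == cfg.n_warmup - 1:
                step = float(np.exp(log_step_bar))
    return draws, n_accept / max(cfg.n_draws, 1), step


def diagnostics(draws: np.ndarray, names: list | None = None):
    """Split R-hat and bulk ESS per parameter column via arviz.

    ``draws`` has shape (n_chains, n_draws, dim); returns a dict of arrays.
    """
    import arviz as az

    if draws.shape[0] == 1:  # split the single chain for a valid R-hat
        half = draws.shape[1] // 2
        draws = np.stack([draws[0, :half], draws[0, half : 2 * half]])
    rhat = np.empty(draws.shape[-1])
    ess = np.empty(draws.shape[-1])
    for k in range(draws.shape[-1]):
        x = draws[:, :, k]
        rhat[k] = float(az.rhat(az.convert_to_dataset(x)).x)
        ess[k] = float(az.ess(az.convert_to_dataset(x)).x)
    out = {"rhat": rhat, "ess": ess}
    if names is not None:
        out["names"] = list(names)
    return out


def summarize(samples: np.ndarray) -> dict:
    """Posterior summary of a 1-D sample: mean, median, 2.5% and 97.5%."""
    return {
        "mean": float(np.mean(samples)),
        "median": float(np.median(samples)),
        "q2.5": float(np.percentile(samples, 2.5)),
        "q97.5": float(np.percentile(samples, 97.5)),
    }
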