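"""Posterior sampling backend.

All hierarchical fits in this package share the same recipe: a vectorized
log-posterior over an unconstrained parameter vector, a MAP optimization to
locate the mode, and an affine-invariant ensemble sampler (emcee) started in
a tight ball around the MAP. Walkers are treated as chains for split-R-hat;
the ensemble sampler has no divergence concept, so the divergence count is
reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .types import PosteriorDraws


@dataclass
class MCMCConfig:
    """Sampler settings.

    n_steps are post-warmup ensemble steps; total steps = n_warmup + n_steps.
    n_walkers defaults to max(2.5 * ndim rounded up to even, 32). ``thin``
    subsamples the kept steps to limit memory.
    """

    n_warmup: int = 800
    n_steps: int = 800
    n_walkers: Optional[int] = None
    thin: int = 2
    seed: int = 0
    rhat_warn: float = 1.01

    def resolve_walkers(self, ndim: int) -> int:
        if self.n_walkers is not None:
            return max(self.n_walkers, 2 * ndim + 2)
        n = max(32, int(np.ceil(2.5 * ndim)))
        return n + (n % 2)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat over a (chain, draw) array."""
    n = x.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def find_map(
    log_prob: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int = 2000,
) -> np.ndarray:
    """Maximize the log-posterior from x0; fall back to x0 on failure."""

    def neg(z):
        v = log_prob(z[None, :])[0]
        return -v if np.isfinite(v) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter})
    if np.isfinite(res.fun) and log_prob(res.x[None, :])[0] >= log_prob(x0[None, :])[0]:
        return np.asarray(res.x, dtype=float)
    return np.asarray(x0, dtype=float)


def sample_posterior(
    log_prob: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    names: Sequence[str],
    config: MCMCConfig,
    derived: Optional[Callable[[np.ndarray], dict]] = None,
    optimize_first: bool = True,
) -> PosteriorDraws:
    """Draw from a posterior with a vectorized log-density.

    Parameters
    ----------
    log_prob
        Maps an (n_walkers, ndim) array to (n_walkers,) log-densities.
    x0
        Starting point (ndim,), typically a moment-based initializer.
    names
        One name per coordinate of the parameter vector.
    derived
        Optional map from a (n_samples, ndim) matrix of kept draws to a dict
        of extra named draw vectors (each (n_samples,)) appended to the
        result (e.g., cell aggregates, natural-scale transforms).
    """
    import emcee

    ndim = len(x0)
    if len(names) != ndim:
        raise ValueError("names must match parameter dimension")
    n_walkers = config.resolve_walkers(ndim)
    rng = np.random.default_rng(config.seed)

    center = find_map(log_prob, np.asarray(x0, dtype=float)) if optimize_first else np.asarray(x0, dtype=float)
    scale = 1e-3 * np.maximum(1.0, np.abs(center))
    start = center[None, :] + scale * rng.standard_normal((n_walkers, ndim))
    # ensure all starts are finite under the posterior
    lp = log_prob(start)
    bad = ~np.isfinite(lp)
    tries = 0
    while bad.any() and tries < 50:
        start[bad] = center[None, :] + scale * rng.standard_normal((int(bad.sum()), ndim))
        lp = log_prob(start)
        bad = ~np.isfinite(lp)
        tries += 1
    if bad.any():
        raise RuntimeError("could not initialize walkers at finite posterior density")

    # DE moves mix markedly better than the stretch move on the strongly
    # correlated mu/tau directions of ex-Gaussian posteriors.
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    state = sampler.run_mcmc(start, config.n_warmup, progress=False,
                             skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, config.n_steps, progress=False,
                     skip_initial_state_check=True)

    chain = sampler.get_chain(thin=config.thin)        # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)                   # (walkers, steps, ndim)

    draws = {nm: chain[:, :, i] for i, nm in enumerate(names)}
    rhat = {nm: _split_rhat(chain[:, :, i]) for i, nm in enumerate(names)}

    if derived is not None:
        flat = chain.reshape(-1, ndim)
        for nm, vec in derived(flat).items():
            vec = np.asarray(vec)
            draws[nm] = vec.reshape(chain.shape[0], chain.shape[1])
            rhat[nm] = _split_rhat(draws[nm])

    flagged = [nm for nm, r in rhat.items() if np.isfinite(r) and r > config.rhat_warn]
    meta = {
        "n_walkers": n_walkers,
        "n_warmup": config.n_warmup,
        "n_steps": config.n_steps,
        "thin": config.thin,
        "seed": config.seed,
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "rhat_flagged": flagged,
    }
    if flagged:
        warnings.warn(
            f"split-R-hat above {config.rhat_warn} for: {', '.join(flagged[:8])}",
            RuntimeWarning, stacklevel=2,
        )
    return PosteriorDraws(draws=draws, rhat=rhat, divergences=0, meta=meta)
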