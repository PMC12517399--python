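"""Ex-Gaussian (exponentially modified Gaussian) distribution utilities.

The ex-Gaussian is the convolution of a Gaussian N(mu, sigma^2) with an
exponential tail of mean tau = exp(beta_log). It captures the three salient
features of inter-turn response latency distributions: negative support
(overlapping turn starts), a bulk just above zero, and a long right tail of
extended pauses. The density is

    f(x) = 1/tau * exp((mu - x)/tau + sigma^2 / (2 tau^2))
               * Phi((x - mu)/sigma - sigma/tau)

computed in log space with ``scipy.special.log_ndtr`` so that both the
small-tau (Gaussian) limit and deep-tail evaluations stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import log_ndtr

from ._engine import MCMCConfig, sample_posterior
from .types import ExGaussParams, PosteriorDraws

ArrayLike = Union[float, np.ndarray]


def _unpack(params) -> tuple:
    if isinstance(params, ExGaussParams):
        return params.mu_s, params.sigma_s, np.exp(params.beta_log)
    mu, sigma, beta_log = params
    return mu, sigma, np.exp(beta_log)


def exgauss_logpdf(x: ArrayLike, params: ExGaussParams) -> np.ndarray:
    """Log-density of the ex-Gaussian at x (seconds). Finite for finite x."""
    mu, sigma, tau = _unpack(params)
    return _logpdf(np.asarray(x, dtype=float), mu, sigma, tau)


def _logpdf(x: np.ndarray, mu, sigma, tau) -> np.ndarray:
    """Vectorized log-density; mu/sigma/tau broadcast against x."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    tau = np.asarray(tau, dtype=float)
    z = (x - mu) / sigma
    return (-np.log(tau) + (mu - x) / tau + 0.5 * (sigma / tau) ** 2
            + log_ndtr(z - sigma / tau))


def _logsf(x: np.ndarray, mu, sigma, tau) -> np.ndarray:
    """Log survival function log P(X > x), numerically stable.

    Both terms of S(x) = Phi(-z) + exp(g) * Phi(z - sigma/tau) with
    g = (mu - x)/tau + sigma^2/(2 tau^2) are positive, so they combine
    through logaddexp without cancellation.
    """
    z = (x - mu) / sigma
    g = (mu - x) / tau + 0.5 * (sigma / tau) ** 2
    return np.logaddexp(log_ndtr(-z), g + log_ndtr(z - sigma / tau))


def exgauss_logsf(x: ArrayLike, params: ExGaussParams) -> np.ndarray:
    mu, sigma, tau = _unpack(params)
    return _logsf(np.asarray(x, dtype=float), mu, sigma, tau)


def exgauss_cdf(x: ArrayLike, params: ExGaussParams) -> np.ndarray:
    return -np.expm1(exgauss_logsf(x, params))


def exgauss_sample(
    params: ExGaussParams,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Draw n ex-Gaussian variates: Normal(mu, sigma) + Exponential(mean tau)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    mu, sigma, tau = _unpack(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(mu, sigma, size=n) + rng.exponential(tau, size=n)


def exgauss_mean(params: ExGaussParams) -> float:
    mu, _, tau = _unpack(params)
    return float(mu + tau)


def exgauss_var(params: ExGaussParams) -> float:
    _, sigma, tau = _unpack(params)
    return float(sigma**2 + tau**2)


def moment_init(x: np.ndarray) -> ExGaussParams:
    """Method-of-moments initializer (skewness-matched, clipped to validity)."""
    x = np.asarray(x, dtype=float)
    m, s = float(np.mean(x)), float(np.std(x))
    skew = float(np.mean(((x - m) / max(s, 1e-9)) ** 3))
    tau = s * (max(skew, 1e-3) / 2.0) ** (1.0 / 3.0)
    tau = float(np.clip(tau, 1e-3, 0.95 * s + 1e-3))
    sigma = float(np.sqrt(max(s**2 - tau**2, (0.05 * s) ** 2 + 1e-8)))
    return ExGaussParams(mu_s=m - tau, sigma_s=sigma, beta_log=float(np.log(tau)))


@dataclass
class ExGaussPriors:
    """Weakly informative priors on the empirical latency scale (seconds).

    Normal priors on mu, log sigma and beta_log = log tau.
    """

    mu_loc: float = 0.5
    mu_scale: float = 1.0
    log_sigma_loc: float = float(np.log(0.5))
    log_sigma_scale: float = 1.0
    beta_log_loc: float = 0.0
    beta_log_scale: float = 1.0

    def logpdf(self, mu, log_sigma, beta_log):
        return (
            -0.5 * ((mu - self.mu_loc) / self.mu_scale) ** 2
            - 0.5 * ((log_sigma - self.log_sigma_loc) / self.log_sigma_scale) ** 2
            - 0.5 * ((beta_log - self.beta_log_loc) / self.beta_log_scale) ** 2
        )


def fit_exgauss_cell(
    latencies: Sequence[float],
    priors: Optional[ExGaussPriors] = None,
    mcmc: Optional[MCMCConfig] = None,
) -> PosteriorDraws:
    """Posterior over (mu, sigma, beta_log) for a single cell of latencies.

    A no-pooling special case of the hierarchical models, used for parameter
    recovery checks and as a building block for simple contrasts. The
    posterior is sampled over (mu, log sigma, beta_log); draws for sigma on
    the natural scale are attached as a derived parameter.
    """
    x = np.asarray(latencies, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("latencies must be non-empty and finite")
    if x.size < 50:
        warnings.warn(f"only {x.size} observations; posterior will be diffuse",
                      UserWarning, stacklevel=2)
    priors = priors or ExGaussPriors()
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500, n_walkers=64)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma, beta_log = theta[:, 0], theta[:, 1], theta[:, 2]
        log_sigma = np.clip(log_sigma, -12.0, 12.0)
        beta_log = np.clip(beta_log, -12.0, 12.0)
        ll = _logpdf(x[None, :], mu[:, None], np.exp(log_sigma)[:, None],
                     np.exp(beta_log)[:, None]).sum(axis=1)
        return ll + priors.logpdf(mu, log_sigma, beta_log)

    init = moment_init(x)
    x0 = np.array([init.mu_s, np.log(init.sigma_s), init.beta_log])

    def derived(flat: np.ndarray) -> dict:
        return {"sigma": np.exp(flat[:, 1]), "tau": np.exp(flat[:, 2])}

    return sample_posterior(log_prob, x0, ["mu", "log_sigma", "beta_log"],
                            mcmc, derived=derived)


def evidence_ratio(
    draws: Sequence[float],
    direction: str = "greater",
    threshold: float = 0.0,
) -> float:
    """Directed posterior evidence ratio.

    Counts draws on the hypothesized side of ``threshold`` against the rest:
    ER = n_favor / n_against. Returns +inf when every draw favors the
    hypothesis and 0.0 when none does.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("evidence_ratio requires at least one draw")
    if direction == "greater":
        favor = int(np.sum(x > threshold))
    elif direction == "less":
        favor = int(np.sum(x < threshold))
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    against = x.size - favor
    if against == 0:
        return float("inf")
    return favor / against


def contrast_from_draws(diff: np.ndarray, direction: str = "greater"):
    """Summarize draw-wise differences as (mean, 95% CI, evidence ratio)."""
    from .types import ContrastResult

    diff = np.asarray(diff, dtype=float)
    lo, hi = np.percentile(diff, [2.5, 97.5])
    if np.allclose(diff, 0.0):
        er = 1.0  # degenerate self-contrast guard
    else:
        er = evidence_ratio(diff, direction)
    return ContrastResult(estimate=float(np.mean(diff)), ci_low=float(lo),
                          ci_high=float(hi), evidence_ratio=er)
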