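"""Core domain types shared across the pipeline.

Times are seconds internally; reporting layers convert to milliseconds.
All time intervals are closed-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GROUPS = ("autism", "typical")
CONTEXTS = ("matching_parent", "convo_parent", "convo_experimenter")

#: Visits on which each conversational context occurs (1-based weekly visits).
CONTEXT_VISITS = {
    "matching_parent": (1, 2, 3, 4, 5, 6, 7),
    "convo_parent": (2, 4, 6),
    "convo_experimenter": (1, 3, 5, 7),
}


@dataclass
class Utterance:
    """One time-stamped speech unit before turn construction."""

    dyad_id: str
    child_id: str
    group: str
    visit: int
    context: str
    speaker_role: str  # "child" | "adult"
    onset_s: float
    offset_s: float
    token_count: Optional[int] = None
    is_backchannel: Optional[bool] = None
    embedding: Optional[np.ndarray] = None
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"utterance offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )
        if self.speaker_role not in ("child", "adult"):
            raise ValueError(f"unknown speaker_role {self.speaker_role!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Turn:
    """A consolidated conversational turn; turns in a session alternate roles.

    ``onset_s`` is the onset of the first substantial (non-backchannel)
    utterance, so a merged leading backchannel never advances the turn start.
    """

    speaker_role: str
    onset_s: float
    offset_s: float
    source_indices: list = field(default_factory=list)
    merged_backchannel: bool = False
    embedding: Optional[np.ndarray] = None
    token_count: Optional[int] = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class LatencyObservation:
    """One turn with its inter-turn response latency and lagged covariates.

    ``latency_s`` = own turn onset minus the partner's preceding turn offset;
    negative values are overlaps. The session's first turn carries no latency
    and is never emitted as an observation.
    """

    dyad_id: str
    child_id: str
    group: str
    visit: int
    context: str
    speaker_role: str
    turn_index: int
    latency_s: float
    is_overlap: bool
    prev_partner_latency_s: Optional[float] = None
    prev_self_latency_s: Optional[float] = None
    pred_prev: Optional[float] = None
    pred_own: Optional[float] = None


@dataclass
class ExGaussParams:
    """Ex-Gaussian (exponentially modified Gaussian) parameters for one cell.

    ``beta_log`` is the natural log of the exponential tail *mean* tau in
    seconds (log link); the distribution mean is ``mu_s + exp(beta_log)`` and
    the variance ``sigma_s**2 + exp(beta_log)**2``. Although the tail
    parameter is conventionally called a "rate", it is stored and reported
    here as log tail mean.
    """

    mu_s: float
    sigma_s: float
    beta_log: float

    def __post_init__(self) -> None:
        if not self.sigma_s > 0:
            raise ValueError(f"sigma_s must be positive, got {self.sigma_s}")

    @property
    def tau_s(self) -> float:
        return float(np.exp(self.beta_log))

    @property
    def mean_s(self) -> float:
        return self.mu_s + self.tau_s

    @property
    def var_s2(self) -> float:
        return self.sigma_s**2 + self.tau_s**2


@dataclass
class PosteriorDraws:
    """Named posterior samples with sampler diagnostics.

    ``draws`` maps a parameter name to an array of shape (chain, draw);
    flattened views are available through :meth:`get`.
    """

    draws: dict
    rhat: dict
    divergences: int = 0
    meta: dict = field(default_factory=dict)

    def names(self) -> list:
        return list(self.draws)

    def get(self, name: str) -> np.ndarray:
        """Flattened draws for one parameter."""
        return np.asarray(self.draws[name]).reshape(-1)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return int(np.asarray(first).size)

    def to_csv(self, path) -> None:
        """Persist draws as a long table (parameter, chain, draw, value)."""
        import pandas as pd

        frames = []
        for name, arr in self.draws.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                arr = arr[None, :]
            chain, draw = np.indices(arr.shape)
            frames.append(pd.DataFrame(dict(
                parameter=name, chain=chain.ravel(), draw=draw.ravel(),
                value=arr.ravel())))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def summary(self):
        """Tidy summary table (parameter, mean, ci_low, ci_high, rhat)."""
        import pandas as pd

        rows = []
        for name in self.draws:
            x = self.get(name)
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                dict(parameter=name, mean=float(np.mean(x)), ci_low=float(lo),
                     ci_high=float(hi), rhat=float(self.rhat.get(name, np.nan)))
            )
        return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """Posterior summary of a directed contrast."""

    estimate: float
    ci_low: float
    ci_high: float
    evidence_ratio: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("credible interval must bracket the estimate")


@dataclass
class KappaResult:
    """Chance-corrected inter-annotator agreement over labeled frames."""

    kappa: float
    ci_low: float
    ci_high: float
    percent_agreement: float

    def __post_init__(self) -> None:
        if self.kappa > 1 + 1e-12:
            raise ValueError("kappa cannot exceed 1")
        if not (0.0 <= self.percent_agreement <= 100.0):
            raise ValueError("percent agreement must lie in [0, 100]")


@dataclass
class SkillProfile:
    """Standardized skill scores for one child.

    Z-scored versions are filled by the analysis against the analysis
    sample's mean/SD; missing raw scores stay missing (never imputed).
    """

    child_id: str
    social_cognition: Optional[float] = None
    social_awareness: Optional[float] = None
    social_motivation: Optional[float] = None
    language: Optional[float] = None
    motor: Optional[float] = None
    z: dict = field(default_factory=dict)


SKILL_NAMES = ("social_cognition", "social_awareness", "social_motivation",
               "language", "motor")


@dataclass
class ModelSpec:
    """Configuration of a hierarchical latency (or overlap) model.

    likelihood: one of {"exgaussian", "exgaussian_constant_beta",
    "exgaussian_truncated_positive", "bernoulli_logit"}.
    Covariates are z-scored before entry and get group-by-context varying
    slopes (full interaction). Child random intercepts act on mu with
    group-specific hyper-SDs; visit effects act on mu with a shared hyper-SD.
    """

    outcome: str = "latency"
    likelihood: str = "exgaussian"
    covariates: Sequence[str] = ()
    child_effects: bool = True
    visit_effects: bool = False
    aggregate_weighting: str = "unweighted"  # or "observation"

    def __post_init__(self) -> None:
        valid = {"exgaussian", "exgaussian_constant_beta",
                 "exgaussian_truncated_positive", "bernoulli_logit"}
        if self.likelihood not in valid:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


@dataclass
class DyadSeries:
    """Per-session ordered latency series for both members of a dyad."""

    dyad_id: str
    group: str
    visit: int
    context: str
    child: list = field(default_factory=list)  # LatencyObservation
    adult: list = field(default_factory=list)
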