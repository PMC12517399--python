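"""Synthetic corpora with the study's design and statistical structure.

The generator emulates the longitudinal design: 28 autistic and 20
typically developing children, seven weekly visits, a parent matching game
on every visit, parent conversations on visits 2/4/6 and experimenter
conversations on visits 1/3/5/7, with ~27.7 turns per session. Child (and
adult) inter-turn latencies follow ex-Gaussian cells per group-by-context
(defaults are the study's posterior cell estimates), shifted additively by
child intercepts, visit effects, skill terms, semantic-predictability
terms, and lag-1 self/interpersonal coupling. Turn timelines are assembled
so that re-segmenting the emitted utterance table through the standard
pipeline reproduces the generated latencies exactly.

Overlaps arise naturally from the Gaussian component's negative support; a
separate Bernoulli overlap helper exists for exercising the logistic
overlap model at an exact target proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .semantics import EmbeddingTable
from .types import (CONTEXT_VISITS, CONTEXTS, GROUPS, SKILL_NAMES,
                    ExGaussParams, SkillProfile, Utterance)

#: Study posterior cell estimates used as generating truth
#: (mu seconds, sigma seconds, beta on log-seconds scale).
DEFAULT_CHILD_CELLS: Dict[Tuple[str, str], ExGaussParams] = {
    ("autism", "matching_parent"): ExGaussParams(0.859, 0.618, 0.19),
    ("autism", "convo_parent"): ExGaussParams(0.580, 0.541, -0.35),
    ("autism", "convo_experimenter"): ExGaussParams(0.766, 0.954, -0.26),
    ("typical", "matching_parent"): ExGaussParams(0.952, 0.529, 0.28),
    ("typical", "convo_parent"): ExGaussParams(0.655, 0.601, -0.31),
    ("typical", "convo_experimenter"): ExGaussParams(1.007, 0.898, -0.18),
}

#: Aggregate generating values (seconds / log scale) for reduced designs.
DEFAULT_AGGREGATES = {
    "autism": ExGaussParams(0.735, 0.683, -0.14),
    "typical": ExGaussParams(0.871, 0.658, -0.07),
}

#: Lag-1 coupling slopes (s per s): (interpersonal, self) aggregates.
DEFAULT_COUPLING = {"autism": (0.038, 0.035), "typical": (0.010, 0.013)}

#: Predictability slopes (s per SD): (pred_prev, pred_own) aggregates.
DEFAULT_PRED_SLOPES = {"autism": (-0.028, 0.069), "typical": (-0.032, 0.050)}

#: Skill slopes (s per SD of the pooled z-scored skill), aggregates.
DEFAULT_SKILL_SLOPES = {
    "autism": {"social_cognition": -0.065, "social_awareness": 0.018,
               "social_motivation": 0.055, "language": 0.043, "motor": -0.023},
    "typical": {"social_cognition": -0.257, "social_awareness": 0.236,
                "social_motivation": 0.087, "language": 0.017, "motor": -0.029},
}

#: Raw skill score (mean, SD) per group, for realistic score tables.
SKILL_SCORE_DISTS = {
    "autism": {"social_cognition": (13.71, 5.46), "social_awareness": (10.39, 3.51),
               "social_motivation": (12.36, 6.11), "language": (107.67, 13.15),
               "motor": (82.54, 3.82)},
    "typical": {"social_cognition": (1.8, 2.21), "social_awareness": (2.5, 2.04),
                "social_motivation": (3.0, 2.13), "language": (109.53, 11.40),
                "motor": (85.25, 2.07)},
}

# Turn-duration lognormal calibrated to the observed median 2.87 s and
# mean 5.69 s: mu_ln = log(median), sigma_ln = sqrt(2 log(mean/median)).
_DUR_MU = float(np.log(2.87))
_DUR_SIGMA = float(np.sqrt(2.0 * np.log(5.69 / 2.87)))


@dataclass
class SyntheticConfig:
    """Full generating parameterization of a simulated corpus."""

    n_children: Dict[str, int] = field(
        default_factory=lambda: {"autism": 28, "typical": 20})
    visits: int = 7
    session_scheme: Dict[str, tuple] = field(
        default_factory=lambda: dict(CONTEXT_VISITS))
    turns_per_session_mean: float = 27.7
    turns_floor: int = 4
    child_cells: Dict[Tuple[str, str], ExGaussParams] = field(
        default_factory=lambda: dict(DEFAULT_CHILD_CELLS))
    adult_cells: Optional[Dict[Tuple[str, str], ExGaussParams]] = None
    coupling: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    adult_coupling: Optional[Dict[str, Tuple[float, float]]] = None
    pred_slopes: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRED_SLOPES))
    skill_slopes: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SKILL_SLOPES.items()})
    child_intercept_sd: float = 0.15
    visit_effect_sd: float = 0.05
    duration_lognorm: Tuple[float, float] = (_DUR_MU, _DUR_SIGMA)
    embedding_dim: int = 16
    target_cosine: float = 0.5
    cosine_jitter: float = 0.15
    backchannel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.child_intercept_sd < 0 or self.visit_effect_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if self.turns_floor < 2:
            raise ValueError("turns_floor must be >= 2")
        if not (-1.0 < self.target_cosine < 1.0):
            raise ValueError("target cosine must lie in (-1, 1)")
        if self.turns_per_session_mean <= 0:
            raise ValueError("turns_per_session_mean must be positive")

    def groups(self) -> List[str]:
        return [g for g in GROUPS if self.n_children.get(g, 0) > 0]


@dataclass
class SyntheticCorpus:
    """Generator output: utterance table, skills, embeddings, ground truth."""

    utterances: pd.DataFrame
    skills: List[SkillProfile]
    embeddings: EmbeddingTable
    truth: dict

    def utterance_objects(self) -> List[Utterance]:
        from .turns_io import _utterances_from_frame

        utts = _utterances_from_frame(self.utterances)
        for u, key in zip(utts, self.utterances["embedding_id"]):
            if isinstance(key, str):
                u.embedding = self.embeddings.get(key)
        return utts


def generate_embeddings(
    n: int,
    target_mean_cosine: float = 0.5,
    jitter: float = 0.15,
    d: int = 16,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ordered unit vectors whose successive cosines are ~N(target, jitter).

    Each vector is built by rotating the previous one toward a fresh random
    orthogonal direction so that cos(e_t, e_{t-1}) equals a drawn target
    exactly (clipped into (-0.95, 0.9995) for numerical safety). Returns
    (vectors (n, d), successive cosines (n-1,)).
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    if not (-1.0 < target_mean_cosine < 1.0):
        raise ValueError("target cosine must lie in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vecs = np.empty((n, d))
    v = rng.standard_normal(d)
    vecs[0] = v / np.linalg.norm(v)
    cos = np.clip(rng.normal(target_mean_cosine, jitter, size=max(n - 1, 0)),
                  -0.95, 0.9995)
    for t in range(1, n):
        w = rng.standard_normal(d)
        w -= np.dot(w, vecs[t - 1]) * vecs[t - 1]
        w /= np.linalg.norm(w)
        c = cos[t - 1]
        vecs[t] = c * vecs[t - 1] + np.sqrt(1.0 - c * c) * w
    return vecs, cos


def _draw_skills(cfg: SyntheticConfig, rng: np.random.Generator,
                 children: Dict[str, List[str]]):
    profiles, raw = [], {}
    for g, ids in children.items():
        for ch in ids:
            vals = {nm: rng.normal(*SKILL_SCORE_DISTS[g][nm]) for nm in SKILL_NAMES}
            raw[ch] = vals
            profiles.append(SkillProfile(child_id=ch, **vals))
    mat = pd.DataFrame(raw).T
    sd = mat.std(ddof=0).replace(0.0, np.nan)
    z = ((mat - mat.mean()) / sd).fillna(0.0)  # degenerate column -> no effect
    for p in profiles:
        p.z = {nm: float(z.loc[p.child_id, nm]) for nm in SKILL_NAMES}
    return profiles, z


def generate_corpus(config: Optional[SyntheticConfig] = None) -> SyntheticCorpus:
    """Simulate a full corpus under the configured generating process.

    Child latency at turn t:
        cell mu + child intercept + visit effect + skill terms
        + pred_prev/pred_own terms (z-scored against the configured cosine
          process) + b_interpersonal * latency(t-1) + b_self * latency(t-2)
        + Normal(0, cell sigma) + Exponential(mean exp(cell beta)).
    Adult latencies are analogous without skill terms. Latencies are
    clamped above -0.9 x previous turn duration so onsets stay ordered; the
    clamped value is the ground-truth latency (it is what the timeline
    realizes and what the lags feed on).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    adult_cells = cfg.adult_cells or cfg.child_cells
    adult_coupling = cfg.adult_coupling or cfg.coupling

    children = {g: [f"{g[:3]}{i:03d}" for i in range(cfg.n_children[g])]
                for g in cfg.groups()}
    profiles, zskills = _draw_skills(cfg, rng, children)
    u_child = {ch: rng.normal(0.0, cfg.child_intercept_sd)
               for ids in children.values() for ch in ids}
    v_eff = {(v, c): rng.normal(0.0, cfg.visit_effect_sd)
             for c in CONTEXTS for v in cfg.session_scheme.get(c, ())}

    rows, emb_vectors = [], {}
    gen_latencies = []  # ground-truth latency records
    for g in cfg.groups():
        b_int_c, b_self_c = cfg.coupling[g]
        b_int_a, b_self_a = adult_coupling[g]
        sp, so = cfg.pred_slopes[g]
        for ch in children[g]:
            dyad = f"dy_{ch}"
            skill_shift = sum(cfg.skill_slopes[g].get(nm, 0.0)
                              * float(zskills.loc[ch, nm]) for nm in SKILL_NAMES)
            for ctx in CONTEXTS:
                for visit in cfg.session_scheme.get(ctx, ()):
                    n_turns = max(cfg.turns_floor,
                                  int(rng.poisson(cfg.turns_per_session_mean)))
                    vecs, cosines = generate_embeddings(
                        n_turns, cfg.target_cosine, cfg.cosine_jitter,
                        cfg.embedding_dim, rng)
                    zcos = (cosines - cfg.target_cosine) / cfg.cosine_jitter
                    durations = rng.lognormal(*cfg.duration_lognorm, size=n_turns)
                    onsets = np.empty(n_turns)
                    offsets = np.empty(n_turns)
                    onsets[0] = 0.0
                    offsets[0] = round(durations[0], 6)
                    lat = np.full(n_turns, np.nan)
                    for t in range(1, n_turns):
                        role = "child" if t % 2 == 1 else "adult"
                        cell = (cfg.child_cells if role == "child"
                                else adult_cells)[(g, ctx)]
                        loc = cell.mu_s + v_eff[(visit, ctx)]
                        if role == "child":
                            loc += u_child[ch] + skill_shift
                            bi, bs = b_int_c, b_self_c
                        else:
                            bi, bs = b_int_a, b_self_a
                        if t >= 2:
                            # pred_own for turn t, pred_prev for turn t-1
                            loc += so * zcos[t - 1] + sp * zcos[t - 2]
                            loc += bi * lat[t - 1]
                        if t >= 3:
                            loc += bs * lat[t - 2]
                        draw = (loc + rng.normal(0.0, cell.sigma_s)
                                + rng.exponential(cell.tau_s))
                        draw = max(draw, -0.9 * durations[t - 1])
                        # snap to the 1-microsecond grid of the emitted table so
                        # re-segmenting the timeline reproduces latencies exactly
                        onsets[t] = round(offsets[t - 1] + draw, 6)
                        offsets[t] = round(onsets[t] + durations[t], 6)
                        lat[t] = onsets[t] - offsets[t - 1]
                    for t in range(n_turns):
                        role = "child" if t % 2 == 1 else "adult"
                        key = f"{dyad}_v{visit}_{ctx}_t{t}"
                        emb_vectors[key] = vecs[t]
                        rows.append(dict(
                            dyad_id=dyad, child_id=ch, group=g, visit=visit,
                            context=ctx, speaker_role=role,
                            onset_s=round(onsets[t], 6),
                            offset_s=round(offsets[t], 6),
                            token_count=int(rng.poisson(5.0)) + 1,
                            is_backchannel=False, embedding_id=key,
                        ))
                        if t >= 1:
                            gen_latencies.append(dict(
                                dyad_id=dyad, visit=visit, context=ctx,
                                turn_index=t, speaker_role=role,
                                latency_s=float(lat[t])))
                    if cfg.backchannel_rate > 0:
                        rows.extend(_inject_backchannels(
                            rows, dyad, ch, g, visit, ctx, onsets, offsets,
                            n_turns, cfg.backchannel_rate, rng))
    utt = pd.DataFrame(rows).sort_values(
        ["dyad_id", "visit", "context", "onset_s"]).reset_index(drop=True)
    truth = {
        "config": _config_record(cfg),
        "child_intercepts": {k: float(v) for k, v in u_child.items()},
        "visit_effects": {f"{v}|{c}": float(x) for (v, c), x in v_eff.items()},
        "generated_latencies": gen_latencies,
    }
    return SyntheticCorpus(utterances=utt, skills=profiles,
                           embeddings=EmbeddingTable(emb_vectors), truth=truth)


def _inject_backchannels(rows, dyad, ch, g, visit, ctx, onsets, offsets,
                         n_turns, rate, rng):
    """Brief flagged acknowledgments placed inside the partner's turn."""
    extra = []
    for t in range(1, n_turns):
        if rng.random() >= rate:
            continue
        role = "child" if t % 2 == 1 else "adult"
        span = offsets[t - 1] - onsets[t - 1]
        if span < 0.8:
            continue
        bc_on = onsets[t - 1] + 0.4 * span
        bc_off = min(bc_on + 0.3, offsets[t - 1] - 1e-3)
        if bc_off <= bc_on or bc_on >= onsets[t]:
            continue
        extra.append(dict(dyad_id=dyad, child_id=ch, group=g, visit=visit,
                          context=ctx, speaker_role=role,
                          onset_s=round(bc_on, 6), offset_s=round(bc_off, 6),
                          token_count=1, is_backchannel=True,
                          embedding_id=None))
    return extra


def _config_record(cfg: SyntheticConfig) -> dict:
    rec = asdict(cfg)
    for key in ("child_cells", "adult_cells"):
        val = getattr(cfg, key)
        if val is not None:
            rec[key] = {f"{g}|{c}": [p.mu_s, p.sigma_s, p.beta_log]
                        for (g, c), p in val.items()}
    return rec


def generate_overlap_corpus(
    n_children: int = 10,
    n_sessions: int = 3,
    n_turns: int = 25,
    p_overlap: float = 0.23,
    group: str = "autism",
    context: str = "matching_parent",
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli overlap indicators over a reduced design, as a latency
    observation frame ready for the logistic overlap model.

    Latency magnitudes are nuisance draws; only the sign (the overlap
    indicator) carries the target structure.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_children):
        ch = f"{group[:3]}{i:03d}"
        for s in range(n_sessions):
            for t in range(n_turns):
                ov = bool(rng.random() < p_overlap)
                mag = abs(rng.normal(0.3, 0.2)) + 0.01
                rows.append(dict(
                    dyad_id=f"dy_{ch}", child_id=ch, group=group,
                    visit=s + 1, context=context, speaker_role="child",
                    turn_index=2 * t + 1,
                    latency_s=-mag if ov else mag, is_overlap=ov,
                    prev_partner_latency_s=None, prev_self_latency_s=None,
                    pred_prev=None, pred_own=None))
    return pd.DataFrame(rows)
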