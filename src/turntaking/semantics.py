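"""Semantic predictability of turns from utterance embedding vectors.

Embeddings arrive through a pluggable provider (a precomputed lookup table
or the synthetic generator); no sentence-embedding model is bundled. For a
responding turn t the two scores are

    pred_own  = cos(e_t, e_{t-1})      planning side: how predictable the
                                       speaker's upcoming turn is from the
                                       partner's preceding turn
    pred_prev = cos(e_{t-1}, e_{t-2})  processing side: how predictable the
                                       partner's preceding turn was from its
                                       own predecessor

Scores attach to the responding turn (default pairing policy); z-scored
versions are computed over the analysis corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Turn

logger = logging.getLogger(__name__)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, clamped to [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class EmbeddingTable:
    """Key -> fixed-dimension embedding vector; zero vectors rejected."""

    vectors: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {np.asarray(v).shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        for k, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite embedding for key {k!r}")
            if np.linalg.norm(v) == 0:
                raise ValueError(f"zero embedding for key {k!r}")
            self.vectors[k] = v

    def get(self, key: str) -> Optional[np.ndarray]:
        return self.vectors.get(key)

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingTable":
        """Load from CSV with columns key, v1..vd."""
        df = pd.read_csv(path)
        if "key" not in df.columns:
            raise ValueError("embedding CSV needs a 'key' column")
        vals = df.drop(columns=["key"]).to_numpy(dtype=float)
        return cls({str(k): vals[i] for i, k in enumerate(df["key"])})

    def to_csv(self, path) -> None:
        keys = list(self.vectors)
        mat = np.array([self.vectors[k] for k in keys])
        df = pd.DataFrame(mat, columns=[f"v{i+1}" for i in range(mat.shape[1])])
        df.insert(0, "key", keys)
        df.to_csv(path, index=False)


@dataclass
class PredictabilityScores:
    """Raw and z-scored predictability per turn index within a session list."""

    pred_prev: Dict[int, float] = field(default_factory=dict)
    pred_own: Dict[int, float] = field(default_factory=dict)
    z_prev: Dict[int, float] = field(default_factory=dict)
    z_own: Dict[int, float] = field(default_factory=dict)


def score_predictability(
    turns: Sequence[Turn],
    zscore: bool = True,
) -> PredictabilityScores:
    """Score each turn from index 2 onward (0-based) against its two
    predecessors. Turns missing an embedding (or whose predecessors are
    missing one) get no score — logged, not an error. Z-scores use the
    mean/SD of the non-missing raw scores in this call; pass the whole
    analysis corpus at once for corpus-level standardization.
    """
    scores = PredictabilityScores()
    for t in range(2, len(turns)):
        e0, e1, e2 = (turns[t - 2].embedding, turns[t - 1].embedding,
                      turns[t].embedding)
        if e0 is None or e1 is None or e2 is None:
            logger.info("turn %d skipped: missing embedding", t)
            continue
        scores.pred_own[t] = cosine_similarity(e2, e1)
        scores.pred_prev[t] = cosine_similarity(e1, e0)
    if zscore:
        for raw, zed in ((scores.pred_prev, scores.z_prev),
                         (scores.pred_own, scores.z_own)):
            if not raw:
                continue
            vals = np.array(list(raw.values()))
            sd = vals.std()
            mean = vals.mean()
            for k, v in raw.items():
                zed[k] = (v - mean) / sd if sd > 0 else 0.0
    return scores


def attach_predictability(observations, sessions_turns, zscore_corpus=True):
    """Fill pred_prev / pred_own on latency observations from scored turns.

    ``sessions_turns`` maps (dyad_id, visit, context) -> turn list. Raw
    cosines are collected over all sessions first so the z-scoring is
    corpus-wide, then written back onto each observation matching its
    ``turn_index``.
    """
    raw = {}  # (key, turn_index) -> (prev, own)
    all_prev, all_own = [], []
    for key, turns in sessions_turns.items():
        s = score_predictability(turns, zscore=False)
        for t in s.pred_own:
            raw[(key, t)] = (s.pred_prev[t], s.pred_own[t])
            all_prev.append(s.pred_prev[t])
            all_own.append(s.pred_own[t])
    if not raw:
        return observations
    mp, sp = float(np.mean(all_prev)), float(np.std(all_prev))
    mo, so = float(np.mean(all_own)), float(np.std(all_own))
    for o in observations:
        key = (o.dyad_id, o.visit, o.context)
        got = raw.get((key, o.turn_index))
        if got is None:
            continue
        pv, ow = got
        if zscore_corpus:
            o.pred_prev = (pv - mp) / sp if sp > 0 else 0.0
            o.pred_own = (ow - mo) / so if so > 0 else 0.0
        else:
            o.pred_prev, o.pred_own = pv, ow
    return observations


def corpus_latencies_with_predictability(
    utterances,
    policy=None,
    min_tokens: Optional[int] = None,
):
    """Segment a corpus and attach corpus-standardized predictability scores.

    Runs turn construction and latency computation per session, scores every
    session's turn embeddings, and z-scores the raw cosines over the whole
    corpus before writing them onto the observations. ``min_tokens`` applies
    the short-utterance exclusion before scoring (control analysis).
    """
    from .turns_io import compute_latencies, iter_sessions, merge_backchannels

    observations = []
    sessions_turns = {}
    for meta, sess in iter_sessions(list(utterances)):
        turns = merge_backchannels(sess, policy=policy)
        if min_tokens is not None:
            turns = filter_short_utterances(turns, min_tokens=min_tokens)
        observations.extend(compute_latencies(turns, meta))
        sessions_turns[(meta["dyad_id"], meta["visit"], meta["context"])] = turns
    return attach_predictability(observations, sessions_turns)


def filter_short_utterances(
    turns: Sequence[Turn],
    min_tokens: int = 3,
) -> List[Turn]:
    """Drop turns under ``min_tokens`` tokens and re-merge to alternation.

    Used by the short-utterance control analysis. After removal, adjacent
    same-role turns are consolidated (onset of the first, offset of the
    last) so the ABABAB contract holds for downstream scoring and fitting.
    """
    kept = [t for t in turns if t.token_count is not None and t.token_count >= min_tokens]
    out: List[Turn] = []
    for t in kept:
        if out and out[-1].speaker_role == t.speaker_role:
            prev = out[-1]
            prev.offset_s = max(prev.offset_s, t.offset_s)
            prev.source_indices = list(prev.source_indices) + list(t.source_indices)
            if t.token_count is not None:
                prev.token_count = (prev.token_count or 0) + t.token_count
        else:
            out.append(Turn(speaker_role=t.speaker_role, onset_s=t.onset_s,
                            offset_s=t.offset_s,
                            source_indices=list(t.source_indices),
                            merged_backchannel=t.merged_backchannel,
                            embedding=t.embedding, token_count=t.token_count))
    return out
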