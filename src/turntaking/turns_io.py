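"""Utterance I/O, turn construction, and inter-turn latency computation.

A session is one recording of one dyad (child + adult) in one context on one
visit. Utterances are merged into strictly alternating turns (ABABAB): runs
of same-speaker utterances are consolidated, and backchannels are folded
into the same speaker's next substantial turn, with the turn onset taken
from the substantial material so that a leading "mm-hm" never advances the
measured response time. Latency of a turn is its onset minus the offset of
the partner's preceding turn; negative latencies are overlaps, and a
latency of exactly zero counts as a gap.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import LatencyObservation, Turn, Utterance

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["dyad_id", "child_id", "group", "visit", "context",
                    "speaker_role", "onset_s", "offset_s"]
OPTIONAL_COLUMNS = ["token_count", "is_backchannel", "text", "embedding_id"]


class FormatError(ValueError):
    """A required column/tier is missing or the file layout is wrong."""


class DataError(ValueError):
    """Rows are present but their values are unusable."""


# ---------------------------------------------------------------------------
# reading / writing


def _utterances_from_frame(df: pd.DataFrame) -> List[Utterance]:
    out = []
    for _, row in df.iterrows():
        emb = None
        out.append(Utterance(
            dyad_id=str(row["dyad_id"]), child_id=str(row["child_id"]),
            group=str(row["group"]), visit=int(row["visit"]),
            context=str(row["context"]), speaker_role=str(row["speaker_role"]),
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            token_count=(int(row["token_count"])
                         if "token_count" in row and pd.notna(row.get("token_count")) else None),
            is_backchannel=(bool(row["is_backchannel"])
                            if "is_backchannel" in row and pd.notna(row.get("is_backchannel")) else None),
            text=(str(row["text"]) if "text" in row and pd.notna(row.get("text")) else None),
            embedding=emb,
        ))
    return out


def utterances_to_frame(utterances: Sequence[Utterance]) -> pd.DataFrame:
    rows = []
    for u in utterances:
        rows.append(dict(
            dyad_id=u.dyad_id, child_id=u.child_id, group=u.group,
            visit=u.visit, context=u.context, speaker_role=u.speaker_role,
            onset_s=u.onset_s, offset_s=u.offset_s,
            token_count=u.token_count, is_backchannel=u.is_backchannel,
            text=u.text,
        ))
    return pd.DataFrame(rows)


def read_utterances(
    path,
    format: str = "csv",
    metadata: Optional[dict] = None,
    units: str = "s",
) -> List[Utterance]:
    """Read a session/corpus utterance table; returns utterances sorted by onset.

    ``format`` is one of {"csv", "tsv", "textgrid"}. For TextGrid input,
    ``metadata`` must carry the session descriptor (dyad_id, child_id, group,
    visit, context) and may carry ``tier_roles`` mapping tier names to
    "child"/"adult" (defaults to tiers literally named child/adult).
    ``units="ms"`` divides input times by 1000.
    """
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        if units == "ms":
            df = df.assign(onset_s=df["onset_s"] / 1000.0,
                           offset_s=df["offset_s"] / 1000.0)
        bad_nan = df.index[df["onset_s"].isna() | df["offset_s"].isna()].tolist()
        if bad_nan:
            raise DataError(f"non-numeric onset/offset on rows {bad_nan}")
        bad = df.index[df["offset_s"] <= df["onset_s"]].tolist()
        if bad:
            raise DataError(f"offset <= onset on rows {bad}")
        utts = _utterances_from_frame(df)
    elif format == "textgrid":
        utts = _read_textgrid(path, metadata or {}, units=units)
    else:
        raise FormatError(f"unknown format {format!r}")
    return sorted(utts, key=lambda u: (u.dyad_id, u.visit, u.context, u.onset_s))


def write_utterances(utterances: Sequence[Utterance], path, format: str = "csv") -> None:
    df = utterances_to_frame(utterances)
    df.to_csv(path, sep="\t" if format == "tsv" else ",", index=False,
              float_format="%.6f")


_TG_NUM = re.compile(r"(?:xmin|xmax)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"((?:[^"]|"")*)"')
_TG_NAME = re.compile(r'name\s*=\s*"((?:[^"]|"")*)"')


def _read_textgrid(path, metadata: dict, units: str = "s") -> List[Utterance]:
    """Minimal parser for Praat long-format TextGrid interval tiers."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        content = fh.read()
    if "IntervalTier" not in content:
        raise FormatError("no IntervalTier found in TextGrid")
    tier_roles = metadata.get("tier_roles", {"child": "child", "adult": "adult"})
    scale = 1e-3 if units == "ms" else 1.0
    utts: List[Utterance] = []
    # split into tier blocks
    blocks = re.split(r'class\s*=\s*"IntervalTier"', content)[1:]
    for block in blocks:
        mname = _TG_NAME.search(block)
        if not mname:
            raise FormatError("IntervalTier without a name")
        tier = mname.group(1)
        role = tier_roles.get(tier)
        if role is None:
            continue
        # first xmin/xmax pair is the tier range; intervals follow
        nums = [float(v) for v in _TG_NUM.findall(block)]
        texts = _TG_TEXT.findall(block)
        ivals = list(zip(nums[2::2], nums[3::2]))
        if len(ivals) != len(texts):
            raise FormatError(f"malformed intervals in tier {tier!r}")
        for (x0, x1), txt in zip(ivals, texts):
            if not txt.strip():
                continue
            utts.append(Utterance(
                dyad_id=str(metadata.get("dyad_id", "d0")),
                child_id=str(metadata.get("child_id", "c0")),
                group=str(metadata.get("group", "typical")),
                visit=int(metadata.get("visit", 1)),
                context=str(metadata.get("context", "convo_parent")),
                speaker_role=role,
                onset_s=x0 * scale, offset_s=x1 * scale,
                token_count=len(txt.split()),
                text=txt.replace('""', '"'),
            ))
    return utts


# ---------------------------------------------------------------------------
# backchannel policy and turn construction


@dataclass
class BackchannelPolicy:
    """How to decide that an utterance is a backchannel.

    The input flag wins when present. Otherwise the heuristic marks short
    (token_count <= max_tokens AND duration <= max_duration_s) utterances
    that are at least partially overlapped by the other speaker's speech.
    """

    use_flag: bool = True
    max_tokens: int = 2
    max_duration_s: float = 1.0

    def classify(self, utterances: Sequence[Utterance]) -> np.ndarray:
        flags = np.zeros(len(utterances), dtype=bool)
        for i, u in enumerate(utterances):
            if self.use_flag and u.is_backchannel is not None:
                flags[i] = bool(u.is_backchannel)
                continue
            if u.token_count is None or u.token_count > self.max_tokens:
                continue
            if u.duration_s > self.max_duration_s:
                continue
            overlapped = any(
                v.speaker_role != u.speaker_role
                and v.onset_s < u.offset_s and u.onset_s < v.offset_s
                for v in utterances
            )
            flags[i] = overlapped
        return flags


def _merge_embeddings(parts: List[Utterance]):
    embs = [(p.embedding, p.token_count or 1) for p in parts if p.embedding is not None]
    if not embs:
        return None
    v = np.sum([e * w for e, w in embs], axis=0)
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def merge_backchannels(
    utterances: Sequence[Utterance],
    policy: Optional[BackchannelPolicy] = None,
) -> List[Turn]:
    """Build strictly alternating turns from one session's sorted utterances.

    Consecutive same-speaker utterances consolidate into a single turn.
    A backchannel is held back and folded into the same speaker's next
    substantial turn (its tokens count, but the turn onset comes from the
    substantial utterance). Trailing backchannels with no subsequent
    substantial same-speaker utterance are dropped to preserve alternation.
    Idempotent: applying the merge to its own output changes nothing.
    """
    utts = sorted(utterances, key=lambda u: (u.onset_s, 0 if u.speaker_role == "adult" else 1))
    if not utts:
        return []
    policy = policy or BackchannelPolicy()
    is_bc = policy.classify(utts)

    turns: List[Turn] = []
    pending: dict = {"child": [], "adult": []}  # backchannels awaiting a host

    for i, u in enumerate(utts):
        role = u.speaker_role
        if is_bc[i]:
            if turns and turns[-1].speaker_role == role:
                # backchannel inside the speaker's own ongoing turn: absorb
                t = turns[-1]
                t.offset_s = max(t.offset_s, u.offset_s)
                t.source_indices.append(i)
                if u.token_count is not None:
                    t.token_count = (t.token_count or 0) + u.token_count
            else:
                pending[role].append((i, u))
            continue
        if turns and turns[-1].speaker_role == role:
            t = turns[-1]
            t.offset_s = max(t.offset_s, u.offset_s)
            t.source_indices.append(i)
            if u.token_count is not None:
                t.token_count = (t.token_count or 0) + u.token_count
            if u.embedding is not None:
                parts = [utts[j] for j in t.source_indices]
                t.embedding = _merge_embeddings(parts)
        else:
            held = pending[role]
            pending[role] = []
            src = [j for j, _ in held] + [i]
            tokens = [utts[j].token_count for j in src]
            token_count = (sum(tc for tc in tokens if tc is not None)
                           if any(tc is not None for tc in tokens) else None)
            turns.append(Turn(
                speaker_role=role,
                onset_s=u.onset_s,  # substantial content sets the onset
                offset_s=max(utts[j].offset_s for j in src),
                source_indices=src,
                merged_backchannel=bool(held),
                token_count=token_count,
                embedding=_merge_embeddings([utts[j] for j in src]),
            ))
    for role, held in pending.items():
        if held:
            logger.info("dropped %d trailing backchannel(s) for %s", len(held), role)
    return turns


def compute_latencies(
    turns: Sequence[Turn],
    metadata: dict,
) -> List[LatencyObservation]:
    """Latency observations for every turn after the first.

    latency(t) = onset(t) - offset(t-1). Both child- and adult-side
    observations are emitted; lagged fields reference the partner's previous
    latency (turn t-1) and the speaker's own previous latency (turn t-2)
    where defined.
    """
    if len(turns) < 2:
        return []
    lat = [None] * len(turns)
    for t in range(1, len(turns)):
        lat[t] = turns[t].onset_s - turns[t - 1].offset_s
    obs = []
    for t in range(1, len(turns)):
        obs.append(LatencyObservation(
            dyad_id=str(metadata["dyad_id"]), child_id=str(metadata["child_id"]),
            group=str(metadata["group"]), visit=int(metadata["visit"]),
            context=str(metadata["context"]),
            speaker_role=turns[t].speaker_role,
            turn_index=t,
            latency_s=float(lat[t]),
            is_overlap=bool(lat[t] < 0),
            prev_partner_latency_s=(float(lat[t - 1]) if t >= 2 else None),
            prev_self_latency_s=(float(lat[t - 2]) if t >= 3 else None),
        ))
    return obs


# ---------------------------------------------------------------------------
# corpus-level convenience


def iter_sessions(utterances: Sequence[Utterance]) -> Iterable[tuple]:
    """Yield (metadata dict, utterance list) per session, in sorted order."""
    keyed: dict = {}
    for u in utterances:
        keyed.setdefault((u.dyad_id, u.visit, u.context), []).append(u)
    for (dyad_id, visit, context) in sorted(keyed):
        sess = sorted(keyed[(dyad_id, visit, context)], key=lambda u: u.onset_s)
        meta = dict(dyad_id=dyad_id, child_id=sess[0].child_id,
                    group=sess[0].group, visit=visit, context=context)
        yield meta, sess


def corpus_latencies(
    utterances: Sequence[Utterance],
    policy: Optional[BackchannelPolicy] = None,
) -> List[LatencyObservation]:
    """Full segmentation pipeline over a multi-session utterance list."""
    obs: List[LatencyObservation] = []
    for meta, sess in iter_sessions(utterances):
        turns = merge_backchannels(sess, policy=policy)
        obs.extend(compute_latencies(turns, meta))
    return obs


def observations_to_frame(observations: Sequence[LatencyObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(dict(
            dyad_id=o.dyad_id, child_id=o.child_id, group=o.group,
            visit=o.visit, context=o.context, speaker_role=o.speaker_role,
            turn_index=o.turn_index, latency_s=o.latency_s,
            is_overlap=o.is_overlap,
            prev_partner_latency_s=o.prev_partner_latency_s,
            prev_self_latency_s=o.prev_self_latency_s,
            pred_prev=o.pred_prev, pred_own=o.pred_own,
        ))
    return pd.DataFrame(rows)
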