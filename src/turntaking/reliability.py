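"""Reliability diagnostics: test-retest and cross-context consistency of
child mean latencies, and frame-based inter-annotator boundary agreement.

Test-retest correlates each child's per-visit mean latency across the
repeated visits of one social context (all seven visits for the matching
game; visits 2, 4, 6 for parent conversations; 1, 3, 5, 7 for experimenter
conversations); pairwise Pearson r values are Fisher-z averaged and the CI
comes from a bootstrap over children (N = 1000 by default).

Boundary agreement discretizes two annotators' segment boundaries into
10-ms frames labeled speech/non-speech and computes Cohen's kappa plus
percent agreement over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .types import CONTEXT_VISITS, KappaResult  # noqa: F401  (re-export)


@dataclass
class ChildContextMeans:
    """child x context x visit mean latencies (seconds).

    Only sessions with at least ``min_obs`` latency observations contribute
    a mean (default 5, configurable).
    """

    table: pd.DataFrame  # columns: child_id, context, visit, mean_latency_s, n
    min_obs: int = 5

    @classmethod
    def from_observations(cls, observations, role: str = "child",
                          min_obs: int = 5) -> "ChildContextMeans":
        from .latency_models import _as_frame

        df = _as_frame(observations)
        df = df[df["speaker_role"] == role]
        g = (df.groupby(["child_id", "context", "visit"])["latency_s"]
               .agg(["mean", "size"]).reset_index()
               .rename(columns={"mean": "mean_latency_s", "size": "n"}))
        g = g[g["n"] >= min_obs].reset_index(drop=True)
        return cls(table=g, min_obs=min_obs)

    def by_context(self, context: str) -> pd.DataFrame:
        """Wide child x visit matrix of means for one context."""
        sub = self.table[self.table["context"] == context]
        return sub.pivot(index="child_id", columns="visit",
                         values="mean_latency_s")

    def child_context_means(self) -> pd.DataFrame:
        """child x context means (averaged over visits)."""
        return (self.table.groupby(["child_id", "context"])["mean_latency_s"]
                .mean().unstack("context"))


def _fisher_avg_r(wide: pd.DataFrame, visits: Sequence[int]) -> float:
    rs = []
    cols = [v for v in visits if v in wide.columns]
    for i in range(len(cols)):
        for k in range(i + 1, len(cols)):
            pair = wide[[cols[i], cols[k]]].dropna()
            if len(pair) < 3 or pair.std().min() == 0:
                continue
            r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            rs.append(np.clip(r, -0.999999, 0.999999))
    if not rs:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(rs))))


def test_retest(
    means: ChildContextMeans,
    context: str,
    n_boot: int = 1000,
    seed: int = 0,
    visits: Optional[Sequence[int]] = None,
):
    """Fisher-z-averaged pairwise Pearson r across visit pairs, with a
    bootstrap-over-children 95% CI. Returns (r, ci_low, ci_high, pair_table).
    """
    visits = list(visits) if visits is not None else list(CONTEXT_VISITS[context])
    wide = means.by_context(context)
    common = wide.dropna(how="all")
    if len(common) < 3:
        raise ValueError("need >= 3 children with means in this context")
    r = _fisher_avg_r(wide, visits)
    if np.isnan(r):
        raise ValueError("no visit pair with >= 3 common children")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(wide))
    boot = []
    for _ in range(n_boot):
        take = rng.integers(0, len(idx), size=len(idx))
        boot.append(_fisher_avg_r(wide.iloc[take], visits))
    boot = np.array([b for b in boot if np.isfinite(b)])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    pairs = []
    cols = [v for v in visits if v in wide.columns]
    for i in range(len(cols)):
        for k in range(i + 1, len(cols)):
            pair = wide[[cols[i], cols[k]]].dropna()
            if len(pair) >= 3 and pair.std().min() > 0:
                pairs.append(dict(visit_a=cols[i], visit_b=cols[k],
                                  r=float(np.corrcoef(pair.iloc[:, 0],
                                                      pair.iloc[:, 1])[0, 1]),
                                  n_children=len(pair)))
    return float(r), float(lo), float(hi), pd.DataFrame(pairs)


def cross_context_consistency(means: ChildContextMeans) -> pd.DataFrame:
    """3x3 Pearson correlation table of child mean latencies across contexts.

    Symmetric with unit diagonal; entries are NaN where fewer than 3
    children share both contexts.
    """
    wide = means.child_context_means()
    contexts = list(wide.columns)
    if (wide.notna().sum(axis=1) >= 2).sum() < 3:
        raise ValueError("need >= 3 children with means in >= 2 contexts")
    out = pd.DataFrame(np.eye(len(contexts)), index=contexts, columns=contexts)
    for i in range(len(contexts)):
        for k in range(i + 1, len(contexts)):
            pair = wide[[contexts[i], contexts[k]]].dropna()
            r = (float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
                 if len(pair) >= 3 and pair.std().min() > 0 else np.nan)
            out.iloc[i, k] = out.iloc[k, i] = r
    return out


def _frame_labels(segments, duration_s: float, frame_ms: int) -> np.ndarray:
    n = int(round(duration_s * 1000.0 / frame_ms))
    lab = np.zeros(n, dtype=int)
    for on, off in segments:
        i0 = int(np.floor(on * 1000.0 / frame_ms))
        i1 = int(np.ceil(off * 1000.0 / frame_ms))
        lab[max(i0, 0):min(i1, n)] = 1
    return lab


def boundary_kappa(
    annotation_a: Sequence[tuple],
    annotation_b: Sequence[tuple],
    duration_s: Optional[float] = None,
    frame_ms: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Cohen's kappa for speech/non-speech frame labels of two annotations.

    Annotations are (onset_s, offset_s) segment lists spanning the same
    recording; ``duration_s`` defaults to the latest offset. The CI is a
    bootstrap over frames. Returns a KappaResult.
    """
    segs_a = [(float(a), float(b)) for a, b in annotation_a]
    segs_b = [(float(a), float(b)) for a, b in annotation_b]
    if duration_s is None:
        ends = [b for _, b in segs_a + segs_b]
        duration_s = max(ends) if ends else 0.0
    if duration_s <= 0:
        raise ValueError("zero-duration recording")
    la = _frame_labels(segs_a, duration_s, frame_ms)
    lb = _frame_labels(segs_b, duration_s, frame_ms)
    agree = float(np.mean(la == lb)) * 100.0
    kappa = 1.0 if np.array_equal(la, lb) else float(cohen_kappa_score(la, lb))
    rng = np.random.default_rng(seed)
    boot = []
    n = len(la)
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        xa, xb = la[take], lb[take]
        boot.append(1.0 if np.array_equal(xa, xb) else
                    float(cohen_kappa_score(xa, xb)))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return KappaResult(kappa=kappa, ci_low=float(lo), ci_high=float(hi),
                       percent_agreement=agree)
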