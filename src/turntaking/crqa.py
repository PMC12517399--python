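"""Cross-recurrence quantification of child/adult latency series.

The cross-recurrence plot thresholds the absolute difference between every
child latency (rows, index i) and every adult latency (columns, index j):
R[i, j] = 1 iff |child_i - adult_j| <= radius. The recurrence rate is the
fraction of recurrent points; the diagonal asymmetry compares recurrent
mass where the child index leads (i > j) against where the adult index
leads (i < j), normalized by total off-diagonal recurrent mass. Under this
convention a child echoing the adult's tempo one step later (child_i ~
adult_{i-1}) piles mass onto i > j, so positive asymmetry = adult-led.

No delay embedding is used (dimension 1): per-session series are short.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class RecurrencePlot:
    matrix: np.ndarray  # (len(child), len(adult)) binary
    radius: float
    n_child: int
    n_adult: int


@dataclass
class RecurrenceStats:
    recurrence_rate: float  # in [0, 1]
    asymmetry: float        # in [-1, 1]; positive = adult-led


def default_radius(child: Sequence[float], adult: Sequence[float],
                   factor: float = 0.2) -> float:
    """factor x pooled SD of the two series (lands RR in a few-percent band)."""
    pooled = np.concatenate([np.asarray(child, float), np.asarray(adult, float)])
    sd = float(pooled.std())
    return factor * sd if sd > 0 else factor


def build_recurrence(
    child: Sequence[float],
    adult: Sequence[float],
    radius: Optional[float] = None,
) -> RecurrencePlot:
    """Thresholded cross-distance matrix of two latency series (seconds)."""
    c = np.asarray(child, dtype=float)
    a = np.asarray(adult, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValueError("both series must have length >= 2")
    if radius is None:
        radius = default_radius(c, a)
    if not radius > 0:
        raise ValueError("radius must be positive")
    R = (np.abs(c[:, None] - a[None, :]) <= radius).astype(np.uint8)
    return RecurrencePlot(matrix=R, radius=float(radius),
                          n_child=c.size, n_adult=a.size)


def calibrate_radius(
    child: Sequence[float],
    adult: Sequence[float],
    target_rr: float = 0.05,
) -> float:
    """Radius whose recurrence rate is closest to ``target_rr`` (fixed-RR mode)."""
    c = np.asarray(child, dtype=float)
    a = np.asarray(adult, dtype=float)
    d = np.sort(np.abs(c[:, None] - a[None, :]).ravel())
    k = int(np.clip(round(target_rr * d.size) - 1, 0, d.size - 1))
    return float(max(d[k], np.finfo(float).tiny))


def recurrence_stats(plot: RecurrencePlot) -> RecurrenceStats:
    """Recurrence rate and leader-follower diagonal asymmetry."""
    R = plot.matrix
    rr = float(R.mean())
    i, j = np.indices(R.shape)
    lead_child_rows = float(R[i > j].sum())   # child index ahead -> adult led
    lead_adult_cols = float(R[i < j].sum())
    denom = lead_child_rows + lead_adult_cols
    asym = 0.0 if denom == 0 else (lead_child_rows - lead_adult_cols) / denom
    return RecurrenceStats(recurrence_rate=rr, asymmetry=float(asym))


def session_crqa(series, radius: Optional[float] = None,
                 target_rr: Optional[float] = None):
    """Per-session CRQA stats for a list of DyadSeries.

    Returns a tidy DataFrame (dyad_id, visit, context, rr, asymmetry,
    radius). ``target_rr`` switches on fixed-recurrence-rate calibration.
    """
    import pandas as pd

    rows = []
    for s in series:
        c = [o.latency_s for o in s.child]
        a = [o.latency_s for o in s.adult]
        if len(c) < 2 or len(a) < 2:
            continue
        r = (calibrate_radius(c, a, target_rr) if target_rr is not None
             else radius)
        plot = build_recurrence(c, a, r)
        st = recurrence_stats(plot)
        rows.append(dict(dyad_id=s.dyad_id, group=s.group, visit=s.visit,
                         context=s.context, rr=st.recurrence_rate,
                         asymmetry=st.asymmetry, radius=plot.radius))
    return pd.DataFrame(rows)
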