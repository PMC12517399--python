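"""Dyadic temporal adjustment: lag-1 coupling of child and adult latencies.

A bivariate lagged regression (vector autoregression over the alternating
turn sequence): each speaker's latency is conditioned on the partner's
previous latency (interpersonal adjustment) and on the speaker's own
previous latency (self-adjustment), per group-by-context cell, with
ex-Gaussian residuals and correlated dyad-level intercepts across the two
equations. Concurrent dependence between the equations is carried by the
correlated varying effects rather than a simultaneous regressor, avoiding
simultaneity bias.

Surrogate (pseudo) dyads re-pair each child with an adult from a different
dyad in the same group and visit, destroying genuine turn-by-turn
contingency while preserving each speaker's marginal latency distribution
— the permutation null for the coupling slopes.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._engine import MCMCConfig, sample_posterior
from .exgauss import _logpdf, moment_init
from .latency_models import cell_name
from .types import CONTEXTS, GROUPS, DyadSeries, ModelSpec, PosteriorDraws

logger = logging.getLogger(__name__)

ROLES = ("child", "adult")


def build_dyad_series(observations) -> List[DyadSeries]:
    """Group latency observations into per-session child/adult series.

    Sessions with fewer than 2 turns of any role (no usable lag structure)
    are skipped with a log entry. Lag alignment is inherited from the
    segmentation stage: a turn's prev_partner is the latency of the
    immediately preceding turn, prev_self the one before that.
    """
    if isinstance(observations, pd.DataFrame):
        from .turns_io import LatencyObservation

        obs_list = [
            LatencyObservation(**{k: (None if pd.isna(v) else v)
                                  for k, v in row.items()})
            for row in observations.to_dict("records")
        ]
    else:
        obs_list = list(observations)
    keyed: dict = {}
    for o in obs_list:
        keyed.setdefault((o.dyad_id, o.visit, o.context), []).append(o)
    out = []
    for (dyad_id, visit, context) in sorted(keyed):
        sess = sorted(keyed[(dyad_id, visit, context)], key=lambda o: o.turn_index)
        child = [o for o in sess if o.speaker_role == "child"]
        adult = [o for o in sess if o.speaker_role == "adult"]
        if not child or not adult:
            logger.info("session %s skipped: too short for lags",
                        (dyad_id, visit, context))
            continue
        out.append(DyadSeries(dyad_id=str(dyad_id), group=sess[0].group,
                              visit=int(visit), context=str(context),
                              child=child, adult=adult))
    return out


def _coupling_frame(series: Sequence[DyadSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for role, obs in (("child", s.child), ("adult", s.adult)):
            for o in obs:
                if o.prev_partner_latency_s is None or o.prev_self_latency_s is None:
                    continue
                rows.append(dict(dyad_id=s.dyad_id, group=s.group,
                                 context=s.context, role=role,
                                 y=o.latency_s,
                                 prev_partner=o.prev_partner_latency_s,
                                 prev_self=o.prev_self_latency_s))
    return pd.DataFrame(rows)


def fit_var_model(
    series: Sequence[DyadSeries],
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
) -> PosteriorDraws:
    """Fit the bivariate lag-1 coupling model jointly for both roles.

    Posterior parameters are named per role and cell, e.g.
    ``b_interpersonal[child][autism,matching_parent]``; per-group aggregates
    (unweighted cell means) are attached as ``..._agg[child][autism]``.
    Slopes are in seconds of latency change per 1-s increase of the lagged
    latency (multiply by 1000 for the ms-per-s reporting convention).
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig(n_warmup=2000, n_steps=2000)
    dyads = sorted({s.dyad_id for s in series})
    if len(dyads) < 2:
        raise ValueError("need at least 2 dyads")
    df = _coupling_frame(series)
    if df.empty:
        raise ValueError("no observations with complete lag structure")
    if df.groupby("role")["y"].std().min() == 0:
        raise ValueError("degenerate (constant) latency series")

    cells = [(g, c) for g in GROUPS for c in CONTEXTS
             if ((df["group"] == g) & (df["context"] == c)).any()]
    labels = [cell_name(g, c) for g, c in cells]
    nc = len(cells)
    cell_idx = {gc: k for k, gc in enumerate(cells)}
    d_idx = {d: i for i, d in enumerate(dyads)}
    nd = len(dyads)

    role_ix = df["role"].map({"child": 0, "adult": 1}).to_numpy()
    c_ix = np.array([cell_idx[(g, c)] for g, c in zip(df["group"], df["context"])])
    dd_ix = df["dyad_id"].map(d_idx).to_numpy()
    y = df["y"].to_numpy(dtype=float)
    xp = df["prev_partner"].to_numpy(dtype=float)
    xs = df["prev_self"].to_numpy(dtype=float)

    # layout per role: mu(nc), log_sigma(nc), beta_log(nc), b_inter(nc), b_self(nc)
    per_role = 5 * nc
    names = []
    for r in ROLES:
        names += [f"mu[{r}][{l}]" for l in labels]
        names += [f"log_sigma[{r}][{l}]" for l in labels]
        names += [f"beta_log[{r}][{l}]" for l in labels]
        names += [f"b_interpersonal[{r}][{l}]" for l in labels]
        names += [f"b_self[{r}][{l}]" for l in labels]
    sl_z = 2 * per_role
    names += [f"z_dyad[{d}][child]" for d in dyads]
    names += [f"z_dyad[{d}][adult]" for d in dyads]
    names += ["log_sd_dyad[child]", "log_sd_dyad[adult]", "atanh_rho"]
    ndim = sl_z + 2 * nd + 3

    def role_block(theta, r):
        base = r * per_role
        return (theta[:, base:base + nc],
                np.clip(theta[:, base + nc:base + 2 * nc], -8, 8),
                np.clip(theta[:, base + 2 * nc:base + 3 * nc], -8, 8),
                theta[:, base + 3 * nc:base + 4 * nc],
                theta[:, base + 4 * nc:base + 5 * nc])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        lp = np.zeros(theta.shape[0])
        zc = theta[:, sl_z:sl_z + nd]
        za = theta[:, sl_z + nd:sl_z + 2 * nd]
        lsd_c = np.clip(theta[:, -3], -8, 3)
        lsd_a = np.clip(theta[:, -2], -8, 3)
        rho = np.tanh(theta[:, -1])
        # correlated dyad intercepts via Cholesky of [[1,rho],[rho,1]]
        sd_c, sd_a = np.exp(lsd_c), np.exp(lsd_a)
        u_child = sd_c[:, None] * zc
        u_adult = sd_a[:, None] * (rho[:, None] * zc
                                   + np.sqrt(1 - rho[:, None] ** 2) * za)
        lp -= 0.5 * (zc ** 2 + za ** 2).sum(axis=1)
        lp -= 0.5 * (((lsd_c - np.log(0.1)) / 1.0) ** 2
                     + ((lsd_a - np.log(0.1)) / 1.0) ** 2)
        lp -= 0.5 * (theta[:, -1] / 1.0) ** 2
        mu_o = np.zeros((theta.shape[0], y.size))
        sig_o = np.empty_like(mu_o)
        tau_o = np.empty_like(mu_o)
        for r in range(2):
            mu_c, ls_c, bl_c, bi_c, bs_c = role_block(theta, r)
            lp -= 0.5 * (((mu_c - 0.5) / 1.0) ** 2).sum(axis=1)
            lp -= 0.5 * (((ls_c - np.log(0.5)) / 1.0) ** 2).sum(axis=1)
            lp -= 0.5 * (bl_c ** 2).sum(axis=1)
            lp -= 0.5 * ((bi_c / 0.5) ** 2).sum(axis=1)
            lp -= 0.5 * ((bs_c / 0.5) ** 2).sum(axis=1)
            m = (r == role_ix)
            u = u_child if r == 0 else u_adult
            mu_o[:, m] = (mu_c[:, c_ix[m]] + bi_c[:, c_ix[m]] * xp[m]
                          + bs_c[:, c_ix[m]] * xs[m] + u[:, dd_ix[m]])
            sig_o[:, m] = np.exp(ls_c)[:, c_ix[m]]
            tau_o[:, m] = np.exp(bl_c)[:, c_ix[m]]
        ll = _logpdf(y[None, :], mu_o, sig_o, tau_o).sum(axis=1)
        return lp + ll

    x0 = np.zeros(ndim)
    for r, rname in enumerate(ROLES):
        sub_r = df[df["role"] == rname]
        base = r * per_role
        for k in range(nc):
            yk = sub_r["y"].to_numpy()[c_ix[role_ix == r] == k]
            init = moment_init(yk) if yk.size >= 5 else None
            if init is not None:
                x0[base + k] = init.mu_s
                x0[base + nc + k] = np.log(init.sigma_s)
                x0[base + 2 * nc + k] = init.beta_log
            else:
                x0[base + k] = 0.5
                x0[base + nc + k] = np.log(0.4)
    x0[-3] = x0[-2] = np.log(0.1)

    def derived(flat: np.ndarray) -> dict:
        out = {}
        groups_present = sorted({g for g, _ in cells}, key=GROUPS.index)
        for r, rname in enumerate(ROLES):
            base = r * per_role
            bi = flat[:, base + 3 * nc:base + 4 * nc]
            bs = flat[:, base + 4 * nc:base + 5 * nc]
            mu = flat[:, base:base + nc]
            for g in groups_present:
                ks = [k for k, (gg, _) in enumerate(cells) if gg == g]
                out[f"b_interpersonal_agg[{rname}][{g}]"] = bi[:, ks].mean(axis=1)
                out[f"b_self_agg[{rname}][{g}]"] = bs[:, ks].mean(axis=1)
                out[f"mu_agg[{rname}][{g}]"] = mu[:, ks].mean(axis=1)
        out["rho_dyad"] = np.tanh(flat[:, -1])
        return out

    post = sample_posterior(log_prob, x0, names, mcmc, derived=derived)
    post.meta["cells"] = labels
    post.meta["n_obs"] = int(len(df))
    return post


def _derange(items: list, rng: np.random.Generator) -> list:
    """Sattolo shuffle: a uniformly random cyclic permutation (no fixed point)."""
    idx = list(range(len(items)))
    for i in range(len(idx) - 1, 0, -1):
        k = int(rng.integers(0, i))
        idx[i], idx[k] = idx[k], idx[i]
    return idx


def make_surrogate_dyads(
    corpus: Sequence[DyadSeries],
    seed: int = 0,
    method: str = "borrow",
) -> List[DyadSeries]:
    """Re-pair children with adults from different dyads (same group, visit
    and context stratum).

    ``method="borrow"`` keeps each speaker's latency sequence and re-derives
    the lag fields from the re-interleaved sequences, so marginal latency
    multisets are preserved exactly. (Timeline-overlay recomputation lives in
    :func:`make_surrogate_corpus`, which needs the raw utterance timelines.)
    A derangement is guaranteed: no child keeps their own adult.
    """
    if method != "borrow":
        raise ValueError("make_surrogate_dyads supports method='borrow'; "
                         "use make_surrogate_corpus for timeline recomputation")
    rng = np.random.default_rng(seed)
    strata: dict = {}
    for s in corpus:
        strata.setdefault((s.group, s.visit, s.context), []).append(s)
    out: List[DyadSeries] = []
    for key in sorted(strata):
        group = strata[key]
        if len(group) < 2:
            raise ValueError(f"stratum {key} has a single dyad; cannot derange")
        perm = _derange(group, rng)
        for i, s in enumerate(group):
            donor = group[perm[i]]
            out.append(_reinterleave(s, donor))
    return out


def _reinterleave(child_src: DyadSeries, adult_src: DyadSeries) -> DyadSeries:
    """Pair child latencies with a donor's adult latencies; recompute lags."""
    import copy

    c_lat = [o.latency_s for o in child_src.child]
    a_lat = [o.latency_s for o in adult_src.adult]
    n = min(len(c_lat), len(a_lat))
    child_first = (min(o.turn_index for o in child_src.child)
                   < min(o.turn_index for o in child_src.adult))
    seq = []  # (role, latency)
    for i in range(n):
        pair = [("child", c_lat[i]), ("adult", a_lat[i])]
        seq.extend(pair if child_first else pair[::-1])
    # keep trailing unpaired latencies so marginal multisets are preserved
    seq.extend(("child", v) for v in c_lat[n:])
    seq.extend(("adult", v) for v in a_lat[n:])
    new = DyadSeries(dyad_id=f"{child_src.dyad_id}+{adult_src.dyad_id}",
                     group=child_src.group, visit=child_src.visit,
                     context=child_src.context)
    template = {"child": child_src.child, "adult": adult_src.adult}
    counters = {"child": 0, "adult": 0}
    for t, (role, lat) in enumerate(seq):
        src = template[role][counters[role]]
        counters[role] += 1
        o = copy.copy(src)
        o.dyad_id = new.dyad_id
        o.turn_index = t + 1
        o.latency_s = lat
        o.is_overlap = lat < 0
        prev = seq[t - 1] if t >= 1 else None
        prev2 = seq[t - 2] if t >= 2 else None
        o.prev_partner_latency_s = (prev[1] if prev and prev[0] != role else None)
        o.prev_self_latency_s = (prev2[1] if prev2 and prev2[0] == role else None)
        (new.child if role == "child" else new.adult).append(o)
    return new


def make_surrogate_corpus(utterances, seed: int = 0):
    """Timeline-overlay surrogates at the utterance level.

    The surrogate adult's utterance intervals replace the real adult's on
    the child's timeline within each (group, visit, context) stratum; the
    merged event sequence is re-segmented through the standard pipeline
    (ties at identical onsets break adult-first). Returns a new utterance
    list ready for ``corpus_latencies``.
    """
    rng = np.random.default_rng(seed)
    from .turns_io import iter_sessions

    sessions = list(iter_sessions(list(utterances)))
    strata: dict = {}
    for meta, sess in sessions:
        strata.setdefault((meta["group"], meta["visit"], meta["context"]),
                          []).append((meta, sess))
    out = []
    import copy as _copy

    for key in sorted(strata):
        group = strata[key]
        if len(group) < 2:
            raise ValueError(f"stratum {key} has a single dyad; cannot derange")
        perm = _derange(group, rng)
        for i, (meta, sess) in enumerate(group):
            donor_meta, donor_sess = group[perm[i]]
            for u in sess:
                if u.speaker_role == "child":
                    out.append(_copy.copy(u))
            for u in donor_sess:
                if u.speaker_role == "adult":
                    v = _copy.copy(u)
                    v.dyad_id, v.child_id = u.dyad_id, u.child_id
                    v.dyad_id = meta["dyad_id"]
                    v.child_id = meta["child_id"]
                    out.append(v)
    return sorted(out, key=lambda u: (u.dyad_id, u.visit, u.context, u.onset_s))
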