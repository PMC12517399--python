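"""Hierarchical distributional models of inter-turn response latencies.

The base model conditions every ex-Gaussian parameter — the Gaussian
location mu, log scale sigma, and log tail mean beta — on the diagnostic
group by conversational context cell (full interaction, one indicator per
cell so per-cell estimates read off directly). Child-level random
intercepts act on mu with hyper-SDs pooled separately per diagnostic
group; visit-level effects act on mu per cell with a shared hyper-SD.
Covariates (skill scores, predictability) are z-scored and receive a
slope per cell.

Variants: a constant-beta control (one shared tail parameter), a
positive-truncated likelihood for the overlap-excluded control refit, and
a Bernoulli-logit model of overlap rates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._engine import MCMCConfig, sample_posterior
from .exgauss import _logpdf, _logsf, contrast_from_draws, moment_init
from .types import (CONTEXTS, GROUPS, SKILL_NAMES, ContrastResult,
                    LatencyObservation, ModelSpec, PosteriorDraws, SkillProfile)


class CellError(ValueError):
    """A group-by-context cell required by the model has no observations."""


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations.copy()
    from .turns_io import observations_to_frame

    return observations_to_frame(list(observations))


def cell_name(group: str, context: str) -> str:
    return f"{group},{context}"


class _Design:
    """Index arrays and covariate matrix for one model fit."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec,
                 covariate_values: Optional[pd.DataFrame] = None):
        df = df.reset_index(drop=True)
        cells = [(g, c) for g in GROUPS for c in CONTEXTS
                 if ((df["group"] == g) & (df["context"] == c)).any()]
        if not cells:
            raise CellError("no group-by-context cells present")
        self.cells = cells
        self.cell_labels = [cell_name(g, c) for g, c in cells]
        cell_idx = {gc: k for k, gc in enumerate(cells)}
        pairs = list(zip(df["group"], df["context"]))
        if any(p not in cell_idx for p in pairs):
            raise CellError("inconsistent group/context labels")
        self.c = np.array([cell_idx[p] for p in pairs])
        self.n_cells = len(cells)

        self.children = sorted(df["child_id"].unique())
        ch_idx = {ch: j for j, ch in enumerate(self.children)}
        self.j = np.array([ch_idx[ch] for ch in df["child_id"]])
        self.n_children = len(self.children)
        grp_of_child = df.groupby("child_id")["group"].first()
        self.child_group = np.array(
            [GROUPS.index(grp_of_child[ch]) for ch in self.children])
        self.groups_present = sorted({g for g, _ in cells}, key=GROUPS.index)

        self.visit_effects = bool(spec.visit_effects)
        if self.visit_effects:
            vc = sorted(set(zip(df["visit"], df["context"])))
            vc_idx = {p: k for k, p in enumerate(vc)}
            self.v = np.array([vc_idx[p] for p in zip(df["visit"], df["context"])])
            self.n_visitcells = len(vc)
        else:
            self.v = None
            self.n_visitcells = 0

        if covariate_values is not None and len(covariate_values.columns):
            self.Z = covariate_values.to_numpy(dtype=float)
            self.cov_names = list(covariate_values.columns)
        else:
            self.Z = np.zeros((len(df), 0))
            self.cov_names = []
        self.n_cov = self.Z.shape[1]
        self.df = df

    def cell_counts(self) -> np.ndarray:
        return np.bincount(self.c, minlength=self.n_cells)


def _aggregate(dsn: _Design, per_cell: np.ndarray, group: str,
               weighting: str) -> np.ndarray:
    """Aggregate (draws, n_cells) over one group's cells."""
    ks = [k for k, (g, _) in enumerate(dsn.cells) if g == group]
    if not ks:
        raise CellError(f"group {group!r} absent")
    if weighting == "observation":
        w = dsn.cell_counts()[ks].astype(float)
        w /= w.sum()
    else:
        w = np.full(len(ks), 1.0 / len(ks))
    return per_cell[:, ks] @ w


def _fit_latency(df: pd.DataFrame, spec: ModelSpec, mcmc: MCMCConfig,
                 covariates: Optional[pd.DataFrame]) -> PosteriorDraws:
    dsn = _Design(df, spec, covariates)
    y = df["latency_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite latencies in input")
    constant_beta = spec.likelihood == "exgaussian_constant_beta"
    truncated = spec.likelihood == "exgaussian_truncated_positive"
    if truncated and (y < 0).any():
        raise ValueError("truncated-positive likelihood requires nonnegative latencies")

    nc = dsn.n_cells
    n_beta = 1 if constant_beta else nc
    child_fx = spec.child_effects and dsn.n_children >= 2
    n_grp = len(dsn.groups_present)

    names: list = []
    names += [f"mu[{l}]" for l in dsn.cell_labels]
    names += [f"log_sigma[{l}]" for l in dsn.cell_labels]
    names += ([f"beta_log"] if constant_beta
              else [f"beta_log[{l}]" for l in dsn.cell_labels])
    for cov in dsn.cov_names:
        names += [f"b_{cov}[{l}]" for l in dsn.cell_labels]
    sl0 = 2 * nc + n_beta
    sl_child = sl0 + dsn.n_cov * nc
    if child_fx:
        names += [f"z_child[{ch}]" for ch in dsn.children]
        names += [f"log_sd_child[{g}]" for g in dsn.groups_present]
    sl_visit = sl_child + (dsn.n_children + n_grp if child_fx else 0)
    if dsn.visit_effects:
        names += [f"z_visit[{k}]" for k in range(dsn.n_visitcells)]
        names += ["log_sd_visit"]
    ndim = sl_visit + (dsn.n_visitcells + 1 if dsn.visit_effects else 0)

    c, j, v, Z = dsn.c, dsn.j, dsn.v, dsn.Z
    cg = dsn.child_group
    grp_pos = {GROUPS.index(g): gi for gi, g in enumerate(dsn.groups_present)}
    cg_pos = np.array([grp_pos[g] for g in cg])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        W = theta.shape[0]
        mu_c = theta[:, 0:nc]
        ls_c = np.clip(theta[:, nc:2 * nc], -8, 8)
        bl_c = np.clip(theta[:, 2 * nc:2 * nc + n_beta], -8, 8)
        mu = mu_c[:, c]
        for k in range(dsn.n_cov):
            sl = theta[:, sl0 + k * nc: sl0 + (k + 1) * nc]
            mu = mu + Z[None, :, k] * sl[:, c]
        lp = (-0.5 * (((mu_c - 0.5) / 1.0) ** 2).sum(axis=1)
              - 0.5 * (((ls_c - np.log(0.5)) / 1.0) ** 2).sum(axis=1)
              - 0.5 * ((bl_c / 1.0) ** 2).sum(axis=1))
        if dsn.n_cov:
            sl_all = theta[:, sl0:sl0 + dsn.n_cov * nc]
            lp -= 0.5 * ((sl_all / 0.5) ** 2).sum(axis=1)
        if child_fx:
            zc = theta[:, sl_child:sl_child + dsn.n_children]
            lsd = np.clip(theta[:, sl_child + dsn.n_children:
                                sl_child + dsn.n_children + n_grp], -8, 3)
            sd_child = np.exp(lsd)  # (W, n_grp)
            mu = mu + (sd_child[:, cg_pos] * zc)[:, j]
            lp -= 0.5 * (zc ** 2).sum(axis=1)
            lp -= 0.5 * (((lsd - np.log(0.15)) / 1.0) ** 2).sum(axis=1)
        if dsn.visit_effects:
            zv = theta[:, sl_visit:sl_visit + dsn.n_visitcells]
            lsv = np.clip(theta[:, sl_visit + dsn.n_visitcells], -8, 3)
            mu = mu + (np.exp(lsv)[:, None] * zv)[:, v]
            lp -= 0.5 * (zv ** 2).sum(axis=1)
            lp -= 0.5 * ((lsv - np.log(0.05)) ** 2)
        sigma = np.exp(ls_c)[:, c]
        tau = np.exp(bl_c)[:, np.zeros_like(c) if constant_beta else c]
        ll = _logpdf(y[None, :], mu, sigma, tau)
        if truncated:
            ll = ll - _logsf(0.0, mu, sigma, tau)
        return lp + ll.sum(axis=1)

    # moment-based start per cell
    x0 = np.zeros(ndim)
    for k in range(nc):
        sub = y[c == k]
        init = moment_init(sub) if sub.size >= 5 else None
        if init is None:
            x0[k], x0[nc + k] = float(np.mean(sub)) if sub.size else 0.5, np.log(0.4)
            if not constant_beta:
                x0[2 * nc + k] = 0.0
        else:
            x0[k] = init.mu_s
            x0[nc + k] = np.log(init.sigma_s)
            if not constant_beta:
                x0[2 * nc + k] = init.beta_log
    if constant_beta:
        x0[2 * nc] = moment_init(y).beta_log
    if child_fx:
        x0[sl_child + dsn.n_children: sl_child + dsn.n_children + n_grp] = np.log(0.15)
    if dsn.visit_effects:
        x0[sl_visit + dsn.n_visitcells] = np.log(0.05)

    def derived(flat: np.ndarray) -> dict:
        out = {}
        mu_c = flat[:, 0:nc]
        sig_c = np.exp(np.clip(flat[:, nc:2 * nc], -8, 8))
        bl_c = flat[:, 2 * nc:2 * nc + n_beta]
        if constant_beta:
            bl_c = np.repeat(bl_c, nc, axis=1)
        for gi, g in enumerate(dsn.groups_present):
            out[f"mu_agg[{g}]"] = _aggregate(dsn, mu_c, g, spec.aggregate_weighting)
            out[f"sigma_agg[{g}]"] = _aggregate(dsn, sig_c, g, spec.aggregate_weighting)
            out[f"beta_log_agg[{g}]"] = _aggregate(dsn, bl_c, g, spec.aggregate_weighting)
        for k, l in enumerate(dsn.cell_labels):
            out[f"sigma[{l}]"] = sig_c[:, k]
        for ki, cov in enumerate(dsn.cov_names):
            sl = flat[:, sl0 + ki * nc: sl0 + (ki + 1) * nc]
            for g in dsn.groups_present:
                out[f"b_{cov}_agg[{g}]"] = _aggregate(dsn, sl, g,
                                                      spec.aggregate_weighting)
        return out

    post = sample_posterior(log_prob, x0, names, mcmc, derived=derived)
    post.meta["cells"] = dsn.cell_labels
    post.meta["likelihood"] = spec.likelihood
    post.meta["n_obs"] = int(len(df))
    return post


def fit_base_model(
    observations,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    role: str = "child",
) -> PosteriorDraws:
    """Fit the group-by-context distributional latency model.

    ``role`` selects which side's latencies are modeled ("child" default;
    "adult" produces the parallel adult-side table through the identical
    machinery).
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500)
    df = _as_frame(observations)
    df = df[df["speaker_role"] == role]
    if df.empty:
        raise ValueError(f"no observations for role {role!r}")
    ngroups = df.groupby("group")["child_id"].nunique()
    for g, n in ngroups.items():
        if n < 2:
            raise ValueError(f"need >= 2 children per group; group {g!r} has {n}")
    return _fit_latency(df, spec, mcmc, covariates=None)


def refit_excluding_overlaps(
    observations,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    role: str = "child",
) -> PosteriorDraws:
    """Control refit on the positive-latency subset with positive support.

    Mirrors the main model but drops overlaps (latency < 0) and replaces the
    likelihood with a zero-truncated ex-Gaussian.
    """
    spec = spec or ModelSpec()
    spec = ModelSpec(outcome=spec.outcome,
                     likelihood="exgaussian_truncated_positive",
                     covariates=spec.covariates,
                     child_effects=spec.child_effects,
                     visit_effects=spec.visit_effects,
                     aggregate_weighting=spec.aggregate_weighting)
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500)
    full = _as_frame(observations)
    full = full[full["speaker_role"] == role]
    df = full[full["latency_s"] >= 0]
    if df.empty:
        raise ValueError("no nonnegative latencies to fit")
    full_cells = {(g, c) for g, c in zip(full["group"], full["context"])}
    kept_cells = {(g, c) for g, c in zip(df["group"], df["context"])}
    lost = full_cells - kept_cells
    if lost:
        raise CellError(f"cells emptied by overlap exclusion: {sorted(lost)}")
    return _fit_latency(df, spec, mcmc, covariates=None)


def _zscore_skills(skills: Sequence[SkillProfile], child_ids,
                   pooling: str = "pooled") -> pd.DataFrame:
    by_id = {s.child_id: s for s in skills}
    missing = [ch for ch in child_ids if ch not in by_id]
    if missing:
        raise ValueError(f"children without a skill profile: {missing}")
    raw = pd.DataFrame(
        {name: [getattr(by_id[ch], name) for ch in child_ids]
         for name in SKILL_NAMES}, index=list(child_ids))
    z = pd.DataFrame(index=raw.index)
    for name in SKILL_NAMES:
        col = raw[name].astype(float)
        if col.isna().all():
            continue
        sd = col.std(ddof=0)
        if not sd > 0:
            raise ValueError(f"skill {name!r} has zero variance; cannot z-score")
        z[name] = (col - col.mean()) / sd
    return z


def fit_skills_model(
    observations,
    skills: Sequence[SkillProfile],
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    role: str = "child",
) -> PosteriorDraws:
    """Base model plus z-scored skill covariates with per-cell slopes.

    Slopes are reported in seconds per 1 SD of the raw skill score (z-scored
    over the pooled analysis sample); multiply by 1000 for ms per SD.
    """
    spec = spec or ModelSpec(covariates=SKILL_NAMES)
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500)
    df = _as_frame(observations)
    df = df[df["speaker_role"] == role].reset_index(drop=True)
    children = sorted(df["child_id"].unique())
    z = _zscore_skills(skills, children)
    use = [cov for cov in spec.covariates if cov in z.columns]
    if not use:
        raise ValueError("no usable skill covariates")
    covmat = z.loc[df["child_id"], use].reset_index(drop=True)
    keep = ~covmat.isna().any(axis=1)
    return _fit_latency(df[keep.values].reset_index(drop=True), spec, mcmc,
                        covariates=covmat[keep.values].reset_index(drop=True))


def fit_predictability_model(
    observations,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    role: str = "child",
) -> PosteriorDraws:
    """Base model plus z-scored predictability covariates (pred_prev, pred_own).

    pred_prev is the semantic predictability of the partner's preceding turn
    from its own predecessor; pred_own is the predictability of the modeled
    speaker's turn from the partner's preceding turn. Observations missing
    either score are dropped. Slopes in seconds per SD.
    """
    spec = spec or ModelSpec(covariates=("pred_prev", "pred_own"))
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500)
    df = _as_frame(observations)
    df = df[df["speaker_role"] == role].reset_index(drop=True)
    covs = [cv for cv in spec.covariates if cv in ("pred_prev", "pred_own")]
    sub = df.dropna(subset=covs).reset_index(drop=True)
    if sub.empty:
        raise ValueError("predictability scores are missing for all observations")
    covmat = sub[covs].astype(float)
    # enforce z-scale (idempotent when inputs already z-scored)
    covmat = (covmat - covmat.mean()) / covmat.std(ddof=0)
    return _fit_latency(sub, spec, mcmc, covariates=covmat)


def fit_overlap_model(
    observations,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[MCMCConfig] = None,
    role: str = "child",
) -> PosteriorDraws:
    """Multilevel logistic model of per-turn overlap (latency < 0).

    Cell log-odds plus child random intercepts (group-specific hyper-SDs);
    posterior overlap probabilities per cell and per-group aggregates are
    attached on the probability scale as ``p[...]`` / ``p_agg[...]``.
    """
    spec = spec or ModelSpec(outcome="overlap", likelihood="bernoulli_logit")
    mcmc = mcmc or MCMCConfig(n_warmup=1500, n_steps=1500)
    df = _as_frame(observations)
    df = df[df["speaker_role"] == role].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no observations for role {role!r}")
    dsn = _Design(df, spec, None)
    yb = df["is_overlap"].to_numpy(dtype=bool).astype(float)

    nc = dsn.n_cells
    child_fx = spec.child_effects and dsn.n_children >= 2
    n_grp = len(dsn.groups_present)
    names = [f"logit_p[{l}]" for l in dsn.cell_labels]
    if child_fx:
        names += [f"z_child[{ch}]" for ch in dsn.children]
        names += [f"log_sd_child[{g}]" for g in dsn.groups_present]
    ndim = len(names)
    c, j = dsn.c, dsn.j
    grp_pos = {GROUPS.index(g): gi for gi, g in enumerate(dsn.groups_present)}
    cg_pos = np.array([grp_pos[g] for g in dsn.child_group])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        a_c = theta[:, :nc]
        eta = a_c[:, c]
        lp = -0.5 * ((a_c / 1.5) ** 2).sum(axis=1)
        if child_fx:
            zc = theta[:, nc:nc + dsn.n_children]
            lsd = np.clip(theta[:, nc + dsn.n_children:], -8, 3)
            eta = eta + (np.exp(lsd)[:, cg_pos] * zc)[:, j]
            lp -= 0.5 * (zc ** 2).sum(axis=1)
            lp -= 0.5 * (((lsd - np.log(0.3)) / 1.0) ** 2).sum(axis=1)
        # Bernoulli log-lik: y*eta - log(1 + exp(eta)), stable via log_ndtr-free form
        ll = yb[None, :] * eta - np.logaddexp(0.0, eta)
        return lp + ll.sum(axis=1)

    rate = df.groupby(dsn.c)["is_overlap"].mean()
    x0 = np.zeros(ndim)
    for k in range(nc):
        r = float(rate.get(k, 0.2))
        r = min(max(r, 1.0 / (dsn.cell_counts()[k] + 2)), 1 - 1.0 / (dsn.cell_counts()[k] + 2))
        x0[k] = np.log(r / (1 - r))
    if child_fx:
        x0[nc + dsn.n_children:] = np.log(0.3)

    def derived(flat: np.ndarray) -> dict:
        out = {}
        p_c = expit(flat[:, :nc])
        for k, l in enumerate(dsn.cell_labels):
            out[f"p[{l}]"] = p_c[:, k]
        for g in dsn.groups_present:
            out[f"p_agg[{g}]"] = _aggregate(dsn, p_c, g, spec.aggregate_weighting)
        return out

    post = sample_posterior(log_prob, x0, names, mcmc, derived=derived)
    post.meta["cells"] = dsn.cell_labels
    post.meta["likelihood"] = "bernoulli_logit"
    return post


def contrast_cells(
    posterior: PosteriorDraws,
    cell_a,
    cell_b,
    parameter: str = "mu",
    direction: str = "greater",
) -> ContrastResult:
    """Draw-wise contrast a - b of a cell (or aggregate) parameter.

    Cells are (group, context) tuples; a bare group string addresses the
    group aggregate. Returns posterior mean, 95% CI and the directed
    evidence ratio; a self-contrast yields estimate 0 with ER fixed at 1.
    """

    def name_of(cell):
        if isinstance(cell, str):
            return f"{parameter}_agg[{cell}]"
        g, c = cell
        return f"{parameter}[{cell_name(g, c)}]"

    na, nb = name_of(cell_a), name_of(cell_b)
    for nm in (na, nb):
        if nm not in posterior.draws:
            raise KeyError(f"parameter {nm!r} not present in posterior")
    return contrast_from_draws(posterior.get(na) - posterior.get(nb), direction)


def results_table(posterior: PosteriorDraws, scale_ms: Sequence[str] = ("mu", "sigma", "b_")):
    """Tidy results frame; latency-scale parameters reported in ms."""
    df = posterior.summary()

    def to_ms(name):
        return any(name.startswith(p) for p in scale_ms) and not name.startswith("beta")

    for col in ("mean", "ci_low", "ci_high"):
        df[col] = [v * 1000.0 if to_ms(n) else v
                   for n, v in zip(df["parameter"], df[col])]
    df["units"] = ["ms" if to_ms(n) else "-" for n in df["parameter"]]
    return df
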