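# Methods

## The latency model

Inter-turn response latency is defined on strictly alternating turns:
`latency(t) = onset(t) − offset(t−1)`, onset/offset in seconds on a
closed-open interval convention. Negative latencies (overlaps) are retained
— they are data, not errors — and a latency of exactly 0 counts as a gap
(overlap is strict `< 0`). Backchannels are folded into the same speaker's
next substantial turn; the merged turn's onset is the substantial
utterance's onset, so a brief "mm-hm" during the partner's turn never
shortens the measured response time. A trailing backchannel with no
following substantial same-speaker utterance is dropped rather than
promoted, preserving the ABABAB structure. When the input does not flag
backchannels, a configurable heuristic is applied: ≤ 2 tokens, ≤ 1.0 s, and
at least partially overlapped by the other speaker.

Latencies are modeled with an ex-Gaussian likelihood,
`X = N(μ, σ²) + Exp(τ)`: the Gaussian component carries central response
timing (including negative support for overlaps), the exponential tail the
long pauses. The tail parameter is stored and reported as `β = log τ`
(log-seconds, log link); although this parameter is often called a "rate",
here `exp(β)` is the tail *mean* in seconds, so reported values near ±0.3
correspond to tail means near 1 s. Density and survival functions are
computed in log space via `log_ndtr`; the survival function uses
`logaddexp` of two positive terms, so the zero-truncated variant is stable
even deep in the tail.

### Hierarchical structure

The base model conditions μ, log σ and β on every diagnostic-group ×
context cell (one indicator per cell — no reference-cell dummy coding — so
per-cell estimates read off directly). Child random intercepts act on μ
with hyper-SDs estimated separately per diagnostic group (group-specific
pooling); visit effects act on μ per (visit, context) with a shared
hyper-SD and are off by default at desk scales, where they are not
identifiable. Covariates (z-scored skills, z-scored predictability) get one
slope per cell on μ. Aggregate estimates are the unweighted mean of a
group's cell-level posteriors (observation-weighted is available); the
unweighted default keeps aggregates comparable across groups with different
session counts per context.

Priors (weakly informative on the empirical latency scale, configurable):
μ ~ N(0.5 s, 1 s); log σ ~ N(log 0.5, 1); β ~ N(0, 1); covariate and
coupling slopes ~ N(0, 0.5); random-effect z-scores standard normal
(non-centered) with log hyper-SD ~ N(log 0.15, 1) for child intercepts
(N(log 0.3, 1) on the logit scale for the overlap model; N(log 0.05, 1)
for visit effects). These are declared choices of this package.

Variants: `exgaussian_constant_beta` shares one tail parameter across all
cells (the long-pause control); `exgaussian_truncated_positive` divides by
P(X > 0) for the overlap-excluded control refit; `bernoulli_logit` models
the per-turn overlap indicator with cell log-odds plus child intercepts,
reporting probabilities via the inverse logit.

Directed hypotheses are summarized by evidence ratios: the count of
posterior draws on the hypothesized side of the threshold divided by the
count on the other side; +inf when unanimous, and a self-contrast is
reported with ER fixed at 1.

### Posterior computation

Posteriors are sampled with an affine-invariant ensemble sampler (emcee)
over the unconstrained parameterization (log σ, log SDs, atanh ρ), using
differential-evolution moves, which mix far better than the stretch move on
the strongly anticorrelated μ/τ directions. Each fit starts from a MAP
point found by L-BFGS from method-of-moments initial values, with walkers
in a tight ball around it. Defaults: walkers ≈ max(32, 2.5 × dim), 1500
warmup + 1500 kept steps (thinned by 2) for cell-level fits, 2000–3000 for
the hierarchical models. Walkers are treated as chains for split-R-hat;
fits are flagged (a warning, not an error) when any R-hat exceeds 1.01.
Ensemble samplers have no divergence diagnostic; the divergence count in
results is reported as 0 by construction. Note that μ and τ trade off
strongly in the likelihood, so flagged R-hat values slightly above 1.01 on
those coordinates indicate slow mixing along that ridge rather than a
wrong posterior; estimates stabilize well before the flag clears.

## Coupling model

The dyadic model is a bivariate lag-1 regression over the alternating turn
sequence: each speaker's latency is conditioned on the partner's previous
latency (interpersonal adjustment) and the speaker's own previous latency
(self-adjustment), per group × context cell, with ex-Gaussian residuals
(same likelihood as the base model, for consistency) and dyad-level
intercepts in the two equations drawn from a correlated bivariate normal
(Cholesky parameterization, tanh-transformed correlation). Concurrent
dependence between the equations is carried by the correlated varying
effects rather than by a simultaneous regressor — including the partner's
*current* latency as a regressor would induce simultaneity bias. Lagged
latencies enter raw (uncentered); observations missing a lag (the first
turns of a session) are dropped. Slopes are reported in ms per 1-s increase
of the lagged latency.

Surrogate dyads destroy genuine contingency while preserving each
speaker's marginal behavior: within each (group, visit, context) stratum,
children are re-paired with adults from a different dyad via a Sattolo
cyclic derangement (no self-pairing, uniform over cycles, seeded). Two
surrogate constructions are provided: `borrow` (default) keeps each
speaker's latency sequence and recomputes lag alignment from the
re-interleaved sequences — marginal latency multisets are preserved exactly
(trailing unpaired latencies are kept with missing lags) — and a
timeline-overlay mode (`make_surrogate_corpus`) that overlays the surrogate
adult's utterance intervals on the child's real timeline and re-segments
through the standard pipeline (onset ties break adult-first). The stratum
includes context (not just group and visit) so a surrogate adult always
comes from the same kind of session.

## Reliability and CRQA

Test-retest reliability correlates each child's per-visit mean latency
across the visits of one context (all seven for the matching game; 2/4/6
for parent conversations; 1/3/5/7 for experimenter conversations; session
means require ≥ 5 observations, configurable). Pairwise Pearson r over
visit pairs are Fisher-z averaged — the per-pair table is also returned —
and the 95% CI is a seeded bootstrap over children (N = 1000). Under the
generator's variance components the expected r is the intraclass
correlation σ²_child / (σ²_child + σ²_session); the test suite checks this
closed form. Cross-context consistency is the 3×3 Pearson table of child ×
context means.

Boundary agreement discretizes two annotators' speech segments into 10-ms
frames labeled speech/non-speech and computes Cohen's kappa and percent
agreement over frames, with a seeded bootstrap over frames for the CI.
Frame-based labeling is this package's operationalization; the frame width
is a parameter.

Cross-recurrence: `R[i, j] = 1` iff `|child_i − adult_j| ≤ radius`, rows
child, columns adult, no delay embedding (dimension 1 — per-session series
are short; a documented limitation). Recurrence rate is `mean(R)`;
asymmetry is (recurrent mass with child index > adult index) minus the
reverse, over total off-diagonal recurrent mass, so +1 means fully
adult-led (the child echoing the adult's tempo a step later) and −1 fully
child-led. Default radius is 0.2 × pooled SD of the two series, which
lands the recurrence rate in the conventional few-percent band; a
fixed-rate calibration mode (`target_rr`, default 5%) picks the radius by
order statistics of the cross-distances.

## Synthetic corpora

The generator reproduces the study design: 28 autistic + 20 typically
developing children, 7 weekly visits, a matching game with the parent on
every visit, parent conversations on visits 2/4/6, experimenter
conversations on visits 1/3/5/7 (14 sessions per child; 336 matching-game
sessions at the default size), turns per session ~ Poisson(27.7) with a
floor of 4. Turn durations are lognormal calibrated to the reported median
2.87 s and mean 5.69 s. Child latency at turn t is

    cell μ + child intercept + visit effect + Σ skill-slope × z(skill)
    + slope_own × z(cos(e_t, e_{t−1})) + slope_prev × z(cos(e_{t−1}, e_{t−2}))
    + b_interpersonal × latency(t−1) + b_self × latency(t−2)
    + N(0, cell σ) + Exp(cell τ)

with adult latencies analogous minus the skill terms. Default cell
parameters are the published per-cell estimates; default coupling,
predictability and skill slopes are the published aggregates; adult cell
parameters default to the child's for the same cell (adult-side values are
not printed in the available tables). Between-child intercept SD 0.15 s and
visit-effect SD 0.05 s are declared defaults (the true variance components
are not printed). Coupling enters the location term only — the minimal
structure consistent with slope-style reporting — so the stationary mean is
inflated by ≈ 1/(1 − b_int − b_self); recovery fits regress on the same raw
lags, so slope recovery is unaffected.

Embedding sequences are built on the unit sphere: each vector is an exact
rotation of its predecessor toward a fresh orthogonal direction with
successive cosine drawn from N(target, jitter) (defaults 0.5, 0.15, d=16,
clipped into (−0.95, 0.9995)), so the realized cosine process matches the
configured one exactly and the z-scored predictability used in generation
agrees with the analysis-side standardization. Overlaps arise naturally
from the Gaussian component's negative support; `generate_overlap_corpus`
provides Bernoulli indicators at an exact target proportion for exercising
the logistic model. Timelines are assembled so that re-segmenting the
emitted utterance table reproduces the generated latencies exactly
(timestamps snap to a 1-µs grid; latencies are clamped above −0.9 × the
previous turn's duration so onsets stay ordered — the clamped value *is*
the ground truth, affecting ~0.1% of turns). Optional backchannel injection
places brief flagged acknowledgments inside partner turns to exercise the
merging rule.

What the generator does not emulate: lexical content (embeddings are
geometric, not linguistic), prosody, session dropout, within-session
nonstationarity, and any dependence of σ or τ on the lagged structure.
Passing recovery tests therefore demonstrate that the estimators recover
the mechanisms the generator implements at the study's design size — not
that real corpora satisfy those structural assumptions.

## Problem sizes and numerical choices

Recovery checks run at the design sizes of the corresponding desk-scale
studies: single cells of n = 2000–3000; overlap corpora of 10 children × 3
sessions × 25 turns; coupling corpora of 20 dyads × 4 sessions × 30 turns;
predictability corpora of 20 children × full 14-session scheme. At those
sizes the coupling-slope posterior SD is ≈ 20 ms/s and the predictability
slope SD ≈ 14 ms/SD — individual recoveries scatter around the generating
values accordingly, which the test tolerances reflect. The test suite runs
reduced replicate counts for coverage checks (20 replicates with the
matching binomial tolerance). Degenerate inputs are errors, not silent
repairs: empty cells, constant covariates, single-dyad strata, zero-length
recordings and non-finite latencies all raise with the offending unit
named.
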