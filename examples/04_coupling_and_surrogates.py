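"""Dyadic lag-1 coupling and its surrogate-pair null.

Generates coupled dyads (child and adult each adjust to the partner's and
their own previous latency), fits the bivariate lagged model, then refits
on surrogate dyads - children re-paired with adults from other dyads in the
same group and visit - where the slopes must collapse to zero.
"""

import numpy as np

from turntaking import (ExGaussParams, MCMCConfig, SyntheticConfig,
                        build_dyad_series, corpus_latencies, fit_var_model,
                        generate_corpus, make_surrogate_dyads)

cfg = SyntheticConfig(
    n_children={"autism": 10, "typical": 0},
    session_scheme={"matching_parent": (1, 2, 3), "convo_parent": (),
                    "convo_experimenter": ()},
    child_cells={("autism", "matching_parent"): ExGaussParams(0.735, 0.683, -0.14)},
    coupling={"autism": (0.10, 0.05)},   # strong interpersonal adjustment
    pred_slopes={"autism": (0.0, 0.0)}, skill_slopes={"autism": {}},
    child_intercept_sd=0.0, visit_effect_sd=0.0, seed=5)
series = build_dyad_series(corpus_latencies(generate_corpus(cfg).utterance_objects()))
print(f"{len(series)} sessions from {len({s.dyad_id for s in series})} dyads")

mcmc = MCMCConfig(n_warmup=1200, n_steps=1200, seed=2)
for label, data in [("real dyads", series),
                    ("surrogate dyads", make_surrogate_dyads(series, seed=3))]:
    post = fit_var_model(data, mcmc=mcmc)
    d = post.get("b_interpersonal_agg[child][autism]") * 1000
    lo, hi = np.percentile(d, [2.5, 97.5])
    print(f"  {label:16s} interpersonal slope {d.mean():6.1f} ms/s "
          f"[{lo:.1f}, {hi:.1f}]")
# Real dyads recover ~100 ms/s; surrogates destroy the turn-by-turn
# contingency, so their interval covers zero - the coupling is not an
# artifact of shared vocalization rates.
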