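"""Reliability and recurrence diagnostics on a synthetic corpus.

Computes test-retest reliability of child mean latencies within a context
(bootstrap CI over children), the cross-context consistency table, a
frame-based inter-annotator kappa, and per-session cross-recurrence stats.
"""

from turntaking import (ChildContextMeans, SyntheticConfig, boundary_kappa,
                        build_dyad_series, corpus_latencies,
                        cross_context_consistency, generate_corpus, test_retest)
from turntaking.crqa import session_crqa

corpus = generate_corpus(SyntheticConfig(n_children={"autism": 10, "typical": 8},
                                         seed=21))
obs = corpus_latencies(corpus.utterance_objects())
means = ChildContextMeans.from_observations(obs)

r, lo, hi, pairs = test_retest(means, "matching_parent", n_boot=1000, seed=0)
print(f"test-retest r (matching game, 7 visits): {r:.2f} [{lo:.2f}, {hi:.2f}]")
print("cross-context consistency:")
print(cross_context_consistency(means).round(2))

# two annotators disagreeing slightly on one boundary
ann_a = [(0.0, 2.00), (3.0, 5.0)]
ann_b = [(0.0, 2.10), (3.0, 5.0)]
k = boundary_kappa(ann_a, ann_b, duration_s=6.0, seed=1)
print(f"boundary agreement: kappa={k.kappa:.2f} "
      f"[{k.ci_low:.2f}, {k.ci_high:.2f}], {k.percent_agreement:.1f}% raw")

stats = session_crqa(build_dyad_series(obs), target_rr=0.05)
print("CRQA (fixed 5% recurrence rate), first sessions:")
print(stats.head(4)[["dyad_id", "context", "rr", "asymmetry"]].to_string(index=False))
# Positive asymmetry marks adult-led tempo in a session; near-zero values
# are symmetric dynamics. Test-retest is modest (~0.1-0.2) here because a
# ~27-turn session estimates a child's mean latency with SE ~0.3 s while the
# generator's stable child intercepts have SD 0.15 s - the intraclass
# correlation 0.15^2 / (0.15^2 + 0.3^2) ~ 0.2 is what the bootstrap CI brackets.
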