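"""Directed S1->M1 information flow via conditional Granger causality.

Generates a session with a known S1->M1 coupling edge, computes the
stage conditional GC in both directions with spike-jitter significance,
and prints the verdicts: the planted direction should be significant, the
reverse should not.
"""

from cortexlink import CGC_STAGE_GH, jitter_significance, make_grasp_session, select_top_units

bundle, truth = make_grasp_session(seed=11)
edge = truth.edges[0]
print(f"planted edge: {edge.source} -> {edge.target} "
      f"(latency {edge.latency_ms:.1f} ms, gain {edge.gain})")

top_s1 = [u.unit_id for u in select_top_units(bundle, "S1", 10)]
top_m1 = [u.unit_id for u in select_top_units(bundle, "M1", 10)]
print(f"top-rate selections: {len(top_s1)} S1 units, {len(top_m1)} M1 units")

fwd = jitter_significance(bundle, (edge.source, edge.target),
                          stage=CGC_STAGE_GH, direction="s1m1",
                          cond_cap=2, seed=0)
rev = jitter_significance(bundle, (edge.target, edge.source),
                          stage=CGC_STAGE_GH, direction="m1s1",
                          cond_cap=2, seed=0)
print(f"forward CGC (grasp-and-hold stage): {fwd.observed:.4f} nats, "
      f"null 95th pct {fwd.percentile:.4f} -> significant: {fwd.significant}")
print(f"reverse CGC: {rev.observed:.4f} nats, "
      f"null 95th pct {rev.percentile:.4f} -> significant: {rev.significant}")
# the observed value is the Geweke conditional measure averaged over the
# frequency grid; the null jitters every spike within +/-10 ms 30 times
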