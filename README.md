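# cortexlink

Analysis pipeline for paired sensory–motor cortical recordings during
grasping: how tactile information (surface texture, load) is encoded in S1
and M1, transferred along the S1→M1 pathway, and modulated by intracortical
microstimulation (ICMS) of S1.

It is written for systems neuroscientists working with session-based spike
data (sorted units or threshold-crossing multi-unit channels), a trial
table, a grip-force trace, and stimulation event records.  Because such
datasets are rarely shareable, the package ships a synthetic session
generator with ground truth, so every stage of the pipeline is verifiable
end to end.

## What it computes

* **Tactile tuning** — sliding-window two-way ANOVA effect sizes
  η²ᵢ = SSᵢ / (SS_texture + SS_load + SS_interaction + SS_error)
  per unit, with the Bonferroni-style inclusion rule, peak latencies, and
  stage contrasts (Touching −50–150 ms vs Grasp-and-Hold 350–550 ms).
* **Population decoding** — Gaussian-kernel SVM accuracy time courses and
  unit-dropping curves.
* **Directed connectivity** — nonparametric conditional Granger causality
  between S1 and M1 spike trains: multitaper cross-spectra of 1 ms binned
  counts, Wilson spectral factorization S(f) = H(f)ΣH*(f), the Geweke
  conditional measure F_{j→i|k}(f), spike-jitter (±10 ms, 30 surrogates)
  significance, trial-resampling condition ANOVA, and PCA of CGC
  trajectories.
* **ICMS response mapping** — pulse-aligned rates in the non-blanked
  3–9 ms window vs sham baseline, the pulse-triggered-average
  phase-locking index with a 1000-shuffle null, and the response taxonomy
  (phase-locked / non-phase-locked elicitation, inhibition).
* **Stimulation-pair design** — ranking tactile-sensitive M1 channels and
  selecting S1 site pairs that render tactile levels Distinguishable (D),
  Confusable (C), or minimally perturbed (Weak, W).
* **Modulation indices** — artifact-blanked day-2 decoding and the
  normalized indices I_ACC, decoding Bias, I_F, and I_N, with stage
  summaries and the I_N–I_F correlation analysis.

## Worked example

`examples/granger_flow.py` plants a single S1→M1 coupling edge and tests
both directions:

```
planted edge: S1A_00 -> M1_00 (latency 3.9 ms, gain 3.0)
top-rate selections: 10 S1 units, 10 M1 units
forward CGC (grasp-and-hold stage): 0.0145 nats, null 95th pct 0.0038 -> significant: True
reverse CGC: 0.0006 nats, null 95th pct 0.0015 -> significant: False
```

The forward conditional GC (0.0145 nats, the spectral measure averaged
over the frequency grid) exceeds its jitter-null 95th percentile, so the
planted direction is detected; the reverse direction stays inside its
null.  The other scripts in `examples/` walk through tuning decomposition,
population decoding, ICMS response mapping, and the full two-day
stimulation-design workflow; each prints what its numbers mean.

A thin CLI mirrors the library (`cortexlink simulate|tuning|decode|cgc|
pta|design-stim|indices`); session bundles are plain-text directories
(`manifest.json` + CSV tables).

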