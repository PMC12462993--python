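# Methods

This note documents the models, estimators and design choices behind
`cortexlink`, and what the synthetic sessions do and do not establish.

## Windowed effect decomposition

Per unit and per analysis window (200 ms, stepped 50 ms, aligned to target
touch), trial firing rates are decomposed by a two-way fixed-effects ANOVA
over texture and load.  The effect size per factor is

    eta2_i = SS_i / (SS_texture + SS_load + SS_texture_x_load + SS_error),

with Type-II sums of squares computed by explicit model comparison
(residual sums of squares of nested least-squares fits).  On the balanced
default design Type I and Type II coincide; Type II is the right choice for
the mildly unbalanced cells (25–30 trials) the task produces in practice.
Zero total variance returns all-zero effects with a degenerate flag rather
than NaNs.  The default tuning grid has 23 window starts, −200 to +900 ms;
the protocol states the analysis range as −200–1000 ms with 23 time
points, which pins the convention of counting window *starts* (a 21-window
reading is also arithmetically consistent; the grid is configurable).  The
multiple-comparison threshold is
`alpha / (n_factors * n_windows / n_inclusion)` = 0.05/(3·23/5) ≈ 0.0036,
reported to four decimals; the division by the number of inclusion windows
is part of the stated correction formula, adopted as given rather than
derived.  A unit counts as tactile-sensitive when at least five windows are
significant for texture *or* for load; the interaction factor never counts
toward inclusion.

Stage summaries use windows fully contained in the stage span, so the
200 ms stages T (−50–150 ms) and GH (350–550 ms) each contain exactly one
window.  Stage contrasts use the Wilcoxon signed-rank test (exact below
n = 25, normal approximation with continuity correction above).

## Decoding contract

Classification is deliberately a fixed contract, not a contribution:
scikit-learn `SVC` with a Gaussian kernel, C = 1.0, kernel scale
1/(d·var) (`gamma="scale"`), features standardized on training folds only,
stratified k-fold with a seeded shuffle reused across windows.  Features
are per-unit binned rates, 4 × 50 ms bins per 200 ms window.  Unit-dropping
curves retain the top-k units under an importance ordering (window
eta-squared) or averaged random orderings (10 repeats), and report the
smallest retained fraction reaching 95% of the curve's top accuracy.

## Nonparametric conditional Granger causality

Spike trains are binned at 1 ms, mean-subtracted per trial and window, and
cross-spectra estimated with 3 Slepian tapers (time–bandwidth 2), trials
treated as independent realizations; 300 ms windows give a ~3.3 Hz grid up
to the 500 Hz Nyquist rate.  Wilson's iterative spectral matrix
factorization yields S(f) = H(f) Σ H*(f); the plus operator halves the
zero lag (upper triangle kept) and the shared Nyquist lag — the latter
matters: keeping or dropping that lag entirely stalls convergence at ~1e-3
relative error on estimated spectra, while splitting it converges to
machine precision.  Convergence is declared at a relative update below
1e-9; non-convergence raises with the residual attached.

The conditional measure F_{j→i|k} uses the partition-matrix method: factor
the full system (i, j, k) and the reduced system (i, k); normalize the full
innovations so unit i's noise is uncorrelated with the rest; form
Q(f) = G_ext(f)^{-1} H̃(f) with the reduced transfer function embedded; then

    F(f) = ln[ Σ^(i,k)_ii / ( Q_ii(f) Σ^(i,j,k)_ii Q*_ii(f) ) ].

The reported per-window scalar is the arithmetic mean of F(f) over the
frequency grid (a discrete Geweke integral; reducing the spectrum to one
scalar is this package's documented convention).  Spectral values are
floored at zero — negatives arise only from factorization noise — which
makes the scalar nonnegative; all significance statements compare this
estimator against itself on surrogates, so the floor does not bias
verdicts.  On Gaussian VAR fixtures the estimator agrees with a parametric
Geweke oracle (OLS residual-variance ratio of full vs reduced lagged
regressions) within 15% relative error at 200 trials × 300 samples.

Pair selection takes the top 10 units per region by session-mean rate
(ties broken by unit id); the conditioning set is the target region's
remaining selected units, with a configurable cap for desk-scale runs.
Jitter significance displaces every spike independently and uniformly
within ±10 ms (within trial, re-windowed afterwards), recomputes the stage
CGC 30 times, and flags the pair when the observed value strictly exceeds
the surrogate 95th percentile.  Percentile thresholds use the next-higher
order statistic: at n = 30 the linear-interpolation percentile ran the
nominal-5% test at roughly twice its level.  Stage windows for CGC match
the 300 ms analysis window (T: −100–200 ms, GH: 300–600 ms).  The
condition ANOVA resamples 20% of trials with replacement 20 times per cell
and treats resamples as replicates — a deliberately pseudo-replicated
procedure, kept as specified by the protocol rather than corrected.  PCA of CGC
trajectories concatenates the nine condition time courses per pair,
centers without scaling, and fixes signs so each component's
largest-magnitude loading is positive.

## ICMS response characterization

Only the first 10 ms after each pulse is analyzed; the first 3 ms and the
final 1 ms of each cycle are blanked as artifact, so pulse-related rates
live in [3, 9) ms.  Baseline is the same window after sham (0 µA) pulses.
Elicitation/inhibition is a two-sided rank-sum across pulse epochs at
p < 0.01 (the protocol fixes the threshold; the rank-sum statistic is this
package's choice), with elicitation additionally requiring a
blanking-corrected mean rate of at least 2 Hz — the adopted reading of the
otherwise underspecified "normalized firing rate" guard.  The pulse-triggered average uses 0.5 ms
bins over the non-blanked interval; the phase-locking index is the mean of
the peak bin and its up-to-two existing neighbors (no wraparound) minus
the median bin probability.  Its null samples 20% of pulse epochs (read as
epochs, not channels), redistributes their pooled spikes uniformly over
non-blanked bins, and repeats 1000 times; significance requires strictly
exceeding the 99th percentile.

## Stimulation-pair design

Day-1 channels are ranked by single-channel decoding accuracy (50 ms bins,
0–500 ms, 10-fold CV); "clear firing-rate distinction" is operationalized
as a label-permutation test (200 permutations, p < 0.05).  Candidate sites
must significantly affect at least one sensitive channel.  An assignment
{level → site} is scored as

    score = Σ_ch (FR_T1 − FR_T2) · [effect(site_T1, ch) − effect(site_T2, ch)]

over sensitive channels, using raw measured response-map magnitudes
(estimates, not thresholded values).  Weighting by the signed rate
difference — rather than its sign — keeps marginally tuned channels from
casting full votes and penalizes assignments that would overshoot and
reverse a strongly tuned channel; both failure modes produced reproducible
mis-designs under sign-only scoring.  Sites whose contributions are
substantially mixed in sign (minority sign above one third of the total
magnitude) are avoided; if fewer than two clean sites remain the selection
falls back, with a warning, to all sites with significant effects, since
avoidance is a preference rather than a hard constraint.  The
score-maximizing assignment is D, its swap is C; the W pair minimizes the
count (then summed magnitude) of significantly modulated channels.

## Modulation indices

All day-2 time courses use 200 ms windows stepped 40 ms (5 × 40 ms bins),
aligned to train onset; control trials use the nominal onset (touch + the
session's median 210 ms trigger delay) so blanking and windowing are
identical with and without current.  Within the 1 s train the 3 + 1 ms of
each 10 ms cycle are blanked for training and testing data alike, and bin
rates are corrected for blanked time.  The indices are
I_ACC = (ACC_ICMS − ACC_NONE)/ACC_NONE with the decoder trained on day-1
trials only and channels restricted to significant day-1 tactile effects
(the headline variant trains per channel and averages; a population scope
is available); Bias = (F_decoded − F_real)/F_real from a linear-kernel SVR
with the decoding-bias index taken as the plain difference
Bias_ICMS − Bias_NONE (the bias is already normalized by the real force);
I_F = (F_ICMS − F_NONE)/F_NONE summarized over 300–700 ms; and I_N, the
cross-validated (stratified 5-fold) accuracy of classifying stimulated vs
control trials.  Denominator floors (5% of the peak condition-mean force)
suppress near-zero-force blowups; such windows are emitted as missing.
Stage summaries use GRASP (0–280 ms) and HOLD (400–680 ms); the headline
correlation relates block-mean I_N in 140–500 ms to block-mean I_F in
200–700 ms, with the full cross-window correlation matrix available over
−500–1500 ms.

## The synthetic-session generator

Spikes are a discretized conditionally-Poisson process: Bernoulli per 1 ms
bin with p = 1 − exp(−λΔ), log rate = log baseline + tuning + coupling,
clipped at log(400 Hz).  The log link makes tuning and coupling superpose
multiplicatively and keeps closed-form oracles available.  Defaults encode
the study conditions: 3×3 design, 30 trials per cell (minimum 25) in 18
mirrored blocks (~270 trials); texture tuning peaking near touch
(Gaussian kernel at 50 ms, SD 60 ms) and load tuning during grasp-and-hold
(450 ms, SD 80 ms), each with a sustained component (0.35 of peak) so
tactile information persists into the stimulation window, as it does in
the recorded cortex; S1→M1 coupling through alpha-function kernels at
3–6 ms latency; rest-state trains of 1 s on/3 s off, 14 repetitions per
(site, amplitude, frequency) set with matched shams; day-2 blocks of 60
trials, half stimulated, train onset at touch + 210 ± 30 ms.

Generator choices that matter for the end-to-end checks, all treated as
study conditions: sorted-unit baselines are lognormal around 8 Hz and
threshold-crossing channels around 40 Hz (multi-unit scale); tuning signs
are consistent across the population with probability 0.9 (roughness and
load mostly increase drive); per-site ICMS character is coherent —
each site is drawn nearly purely excitatory or inhibitory, with a per-site
strength in [0.05, 1] and a sparse footprint (~1/3 of channels respond) —
mirroring the distinct spatial response patterns of real stimulation
sites and making both weak and strong candidate sites exist; phase-locked
responses carry a per-pulse hazard of 0.30 at maximum amplitude (scaled
down by amplitude, stepped up 1.3× above 25 Hz), sized so that detected
responses show pulse-triggered peaks ~0.1–0.25 above the baseline bin
probability; sustained (non-phase-locked) elevation and inhibition are
multiplicative (gains 0.30 / 0.40 at full strength).  Two-level day
sessions use adjacent texture levels (condition codes ±0.5, half the
3-level ladder's contrast), with smoother textures requiring more grip
force (texture→force gain −0.25 in arbitrary force units; lower friction
demands a stronger grip).  Grip force rises after touch with a 150 ms time
constant to a condition-dependent plateau; on stimulated trials a
deviation ramps in from 300 ms after train onset proportional (0.003 per
Hz) to the net magnitude of evoked M1 rate change — the magnitude, not the
signed sum, so that stronger neural intervention always produces larger
behavioral deviation, which is the coupling the paired indices are meant
to detect; the proportionality constant has no empirical anchor and is a
free parameter.  Randomness is split into named streams via
`SeedSequence([seed, crc32(name)])`; identical (config, seed) gives
bit-identical bundles.

What the generator does *not* emulate: biophysical membrane dynamics,
electrode geometry and artifact waveforms (artifacts appear only as
blanked intervals), oscillatory population structure, behavioral
variability beyond timing jitter, and any adaptation or plasticity.
Passing end-to-end checks therefore shows that the pipeline recovers the
structure it assumes from data of realistic size and noise — not that the
biological claims hold.

## Verification problem sizes

The validation studies run at desk scale on one core: jitter type-I over
100 independent Poisson ensembles (40 trials, one conditioning unit, 30
surrogates); directionality over 20 two-unit-per-region fixtures;
phase-locking calibration over 200 null channels (1400 pulses each, 1000
shuffles) and ~120 generated phase-locked channels from the
responsive-site regime (site strength 0.6–1.0, the regime of responses
that pass the significance screen); the end-to-end study over 20 synthetic
animals with two day-2 C/D sessions and one C/W session each (reduced
surrogate counts inside the design step: 30 ranking permutations, 5-fold
CV, 100 map shuffles).  Within-seed session averaging mirrors the multiple
sessions each animal contributed.

## Known limitations

* The conditioning set is capped in desk-scale runs; the 11-variate
  full 11-variate setting is available but slow.
* The resampling condition ANOVA is pseudo-replicated by design (resamples
  are not independent observations).
* The design score optimizes a linear proxy of decoder behavior; sessions
  whose best achievable score is near zero yield direction-indeterminate
  C/D pairs, an inherent limit of any selection rule on such maps.
* Index time courses assume the nominal 210 ms trigger delay for control
  trials; real trigger-latency distributions are not modeled beyond
  uniform jitter.
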