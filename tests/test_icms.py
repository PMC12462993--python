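"""Pulse-aligned rates, PTA phase locking, and the response taxonomy."""

from dataclasses import replace

import numpy as np
import pytest

from cortexlink import (
    GeneratorConfig,
    SpikeTrain,
    build_response_map,
    classify_channel_response,
    compute_pta,
    make_rest_icms_session,
    parameter_effect_summary,
    phase_lock_index,
    phase_lock_null,
    pulse_aligned_rates,
)
from cortexlink.icms import ANALYSIS_WINDOW


def train_with(spike_offsets_ms, pulses):
    """Spike train with fixed offsets (ms) after every pulse."""
    times = np.sort(np.concatenate(
        [pulses + off / 1000.0 for off in spike_offsets_ms]))
    return SpikeTrain("ch", 0, "M1", times, sorted=False)


PULSES = np.arange(100) * 0.010 + 5.0   # 100 Hz train


class TestPulseAlignedRates:
    def test_one_spike_per_pulse_is_166_7_hz(self):
        rates = pulse_aligned_rates(train_with([5.0], PULSES), PULSES)
        np.testing.assert_allclose(rates, 1000.0 / 6.0, rtol=1e-9)

    def test_spike_in_blanked_interval_not_counted(self):
        rates = pulse_aligned_rates(train_with([1.0, 9.5], PULSES), PULSES)
        assert not rates.any()

    def test_overlapping_windows_rejected(self):
        fast = np.arange(50) * 0.005   # 200 Hz
        with pytest.raises(ValueError, match="overlap"):
            pulse_aligned_rates(train_with([5.0], fast), fast)

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(0)
        rate, n_pulses = 20.0, 2000
        pulses = np.arange(n_pulses) * 0.010
        times = np.sort(rng.uniform(0, n_pulses * 0.010, rng.poisson(rate * n_pulses * 0.010)))
        est = pulse_aligned_rates(SpikeTrain("u", 0, "M1", times), pulses).mean()
        sem = np.sqrt(rate / 0.006 / n_pulses)
        assert est == pytest.approx(rate, abs=4 * sem)

    def test_blanking_conservation(self):
        # counted time per epoch is exactly span - 3 ms - 1 ms
        assert ANALYSIS_WINDOW == (3.0, 9.0)
        rates = pulse_aligned_rates(train_with([4.0, 8.9], PULSES), PULSES)
        np.testing.assert_allclose(rates, 2 / 0.006, rtol=1e-9)


class TestPhaseLockIndex:
    def test_uniform_pta_is_zero(self):
        assert phase_lock_index(np.full(12, 0.02)) == pytest.approx(0.0)

    def test_single_peak_arithmetic(self):
        prob = np.full(12, 0.01)
        prob[5] = 0.3
        expected = (0.3 + 0.01 + 0.01) / 3 - 0.01
        assert phase_lock_index(prob) == pytest.approx(expected, abs=1e-12)

    def test_edge_peak_uses_available_neighbors(self):
        prob = np.full(12, 0.01)
        prob[0] = 0.3
        assert phase_lock_index(prob) == pytest.approx((0.3 + 0.01) / 2 - 0.01)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        prob = rng.random(12) * 0.3
        base = phase_lock_index(prob)
        assert phase_lock_index(prob + 0.2) == pytest.approx(base, abs=1e-12)

    def test_needs_three_bins(self):
        with pytest.raises(ValueError):
            phase_lock_index(np.array([0.1, 0.2]))


class TestPhaseLockNull:
    def test_deterministic_spike_every_pulse_flagged(self):
        pta = compute_pta(train_with([5.1], PULSES), PULSES)
        res = phase_lock_null(pta, n_shuffles=300, seed=0)
        assert res.significant
        assert res.index > res.null_percentile

    def test_zero_spikes_not_flagged(self):
        pta = compute_pta(SpikeTrain("u", 0, "M1", np.array([])), PULSES)
        res = phase_lock_null(pta, n_shuffles=100, seed=0)
        assert res.index == 0.0
        assert not res.significant

    def test_type_i_rate_near_nominal(self):
        """Poisson channels: ~1% flagged at the 99th percentile (<=4% at 3 SD)."""
        rng = np.random.default_rng(2)
        n_channels, n_flagged = 120, 0
        pulses = np.arange(300) * 0.010
        for c in range(n_channels):
            times = np.sort(rng.uniform(0, 3.0, rng.poisson(40 * 3.0)))
            pta = compute_pta(SpikeTrain("u", 0, "M1", times), pulses)
            res = phase_lock_null(pta, n_shuffles=200, seed=c)
            n_flagged += res.significant
        assert n_flagged / n_channels <= 0.04

    def test_needs_ten_pulses(self):
        pta = compute_pta(train_with([5.0], PULSES[:5]), PULSES[:5])
        with pytest.raises(ValueError):
            phase_lock_null(pta)


class TestClassifyResponse:
    def test_identical_distributions_none(self):
        x = np.ones(200) * 5
        cat, p = classify_channel_response(x, x)
        assert cat == "none"

    def test_strong_elicitation_detected(self):
        rng = np.random.default_rng(3)
        sham = rng.poisson(0.1, 500) / 0.006
        post = rng.poisson(0.3, 500) / 0.006
        cat, p = classify_channel_response(post, sham)
        assert cat == "elicited" and p < 0.01

    def test_low_rate_guard_blocks_elicitation(self):
        rng = np.random.default_rng(4)
        sham = np.zeros(500)
        post = rng.poisson(0.008, 500) / 0.006   # elevated but ~1.3 Hz mean
        cat, _ = classify_channel_response(post, sham, min_rate=2.0)
        assert cat == "none"

    def test_inhibition_detected(self):
        rng = np.random.default_rng(5)
        sham = rng.poisson(0.3, 500) / 0.006
        post = rng.poisson(0.1, 500) / 0.006
        cat, p = classify_channel_response(post, sham)
        assert cat == "inhibited" and p < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_channel_response(np.array([]), np.ones(5))


SMALL = GeneratorConfig(n_m1=6, n_s1a=2, n_s1b=2, n_stim_sites=2,
                        icms_repetitions=6,
                        icms_amplitudes=(20.0, 80.0),
                        icms_frequencies=(25.0, 100.0))


class TestResponseMapRecovery:
    def test_categories_match_ground_truth(self):
        bundle, truth = make_rest_icms_session(
            replace(SMALL, site_strength_range=(0.8, 1.0)), seed=4)
        rmap = build_response_map(bundle, n_shuffles=300, seed=0)
        agree = sum(rmap.entries[k].category == truth.response_map[k]["type"]
                    for k in rmap.entries)
        assert agree / len(rmap.entries) >= 0.8

    def test_zero_gain_session_is_mostly_none(self):
        cfg = replace(SMALL, p_phase_locked=0.0, p_non_phase_locked=0.0,
                      p_inhibited=0.0)
        bundle, _ = make_rest_icms_session(cfg, seed=5)
        rmap = build_response_map(bundle, n_shuffles=100, seed=0)
        frac_none = np.mean([e.category == "none" for e in rmap.entries.values()])
        assert frac_none >= 0.9

    def test_amplitude_ladder_monotone_elicited_proportion(self):
        cfg = replace(SMALL, icms_amplitudes=(20.0, 50.0, 80.0),
                      p_inhibited=0.0, p_phase_locked=0.35,
                      p_non_phase_locked=0.35,
                      site_strength_range=(0.7, 1.0), icms_repetitions=8)
        bundle, _ = make_rest_icms_session(cfg, seed=6)
        summary = parameter_effect_summary(bundle, kind="amplitude",
                                           n_shuffles=100, seed=0)
        elicited = (summary.proportions["phase_locked"]
                    + summary.proportions["non_phase_locked"])
        assert elicited[0] <= elicited[-1]
        assert list(summary.levels) == [20.0, 50.0, 80.0]

    def test_frequency_step_above_25hz(self):
        cfg = replace(SMALL, icms_frequencies=(10.0, 25.0, 50.0, 100.0),
                      p_inhibited=0.0, p_phase_locked=0.5,
                      p_non_phase_locked=0.2,
                      site_strength_range=(0.9, 1.0), icms_repetitions=8)
        bundle, truth = make_rest_icms_session(cfg, seed=7)
        summary = parameter_effect_summary(bundle, kind="frequency",
                                           n_shuffles=100, seed=0)
        mags = summary.magnitudes
        # gain steps up above 25 Hz by construction
        assert np.nanmean(mags[2:]) > np.nanmean(mags[:2])
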