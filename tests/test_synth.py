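"""Synthetic session generator: design structure, determinism, and
ground-truth consistency."""

from dataclasses import replace

import numpy as np
import pytest

from cortexlink import (
    Edge,
    GeneratorConfig,
    ValidationError,
    make_day1_session,
    make_grasp_icms_session,
    make_grasp_session,
    make_rest_icms_session,
)
from cortexlink.session import align_spikes

SMALL = GeneratorConfig(n_m1=4, n_s1a=3, n_s1b=2, trials_per_condition=25,
                        n_edges=1, n_stim_sites=2,
                        icms_repetitions=4,
                        icms_amplitudes=(20.0, 80.0),
                        icms_frequencies=(25.0, 100.0))


class TestGraspSession:
    def test_default_design_structure(self):
        bundle, _ = make_grasp_session(seed=0)
        assert len(bundle.trials) == 270
        table = bundle.trial_table()
        cells = table.groupby(["texture", "load"]).size()
        assert len(cells) == 9
        assert (cells == 30).all()
        assert table["block"].nunique() == 18

    def test_mirrored_block_order(self):
        bundle, _ = make_grasp_session(SMALL, seed=1)
        table = bundle.trial_table()
        order = [tuple(g.iloc[0][["texture", "load"]])
                 for _, g in table.groupby("block", sort=True)]
        assert order[:9] == order[9:][::-1]

    def test_determinism(self):
        b1, _ = make_grasp_session(SMALL, seed=7)
        b2, _ = make_grasp_session(SMALL, seed=7)
        for u1, u2 in zip(b1.units, b2.units):
            np.testing.assert_array_equal(u1.times, u2.times)
        np.testing.assert_array_equal(b1.force.values, b2.force.values)

    def test_different_seeds_differ(self):
        b1, _ = make_grasp_session(SMALL, seed=7)
        b2, _ = make_grasp_session(SMALL, seed=8)
        assert not np.array_equal(b1.units[0].times, b2.units[0].times)

    def test_zero_effects_are_homogeneous_poisson(self):
        cfg = replace(SMALL, tuned_fraction=0.0, n_edges=0)
        bundle, truth = make_grasp_session(cfg, seed=2)
        assert not truth.tuned.any()
        unit = bundle.units[0]
        raster = align_spikes(unit, bundle.trials, span=(-200.0, 1000.0))
        rates = np.array([r.size for r in raster]) / 1.2
        expected = truth.baseline[0]
        sem = np.sqrt(expected / 1.2 / len(raster))
        assert rates.mean() == pytest.approx(expected, abs=4 * sem)

    def test_minimum_trials_enforced(self):
        with pytest.raises(ValidationError):
            make_grasp_session(replace(SMALL, trials_per_condition=20), seed=0)

    def test_coupling_produces_correlogram_peak_at_latency(self):
        """Cross-correlogram oracle: a strong S1->M1 edge at 4 ms produces a
        short-latency peak in the forward correlogram."""
        cfg = replace(SMALL, n_edges=0, tuned_fraction=0.0)
        edge = Edge(source="S1A_00", target="M1_00", latency_ms=4.0,
                    gain=4.0, width_ms=2.0)
        bundle, truth = make_grasp_session(cfg, seed=3, edges=[edge])
        src = next(u for u in bundle.units if u.unit_id == "S1A_00")
        tgt = next(u for u in bundle.units if u.unit_id == "M1_00")
        lags = np.arange(-20, 21)
        counts = np.zeros(lags.size)
        for s_rel, t_rel in zip(align_spikes(src, bundle.trials, span=(0, 1000)),
                                align_spikes(tgt, bundle.trials, span=(0, 1000))):
            for s in s_rel:
                d = np.round(t_rel - s).astype(int)
                d = d[(d >= -20) & (d <= 20)]
                counts += np.bincount(d + 20, minlength=41)
        peak_lag = lags[np.argmax(counts)]
        assert 3 <= peak_lag <= 7    # latency 4 ms + kernel peak ~2 ms


class TestRestSession:
    def test_pulse_arithmetic(self):
        bundle, _ = make_rest_icms_session(SMALL, seed=0)
        trains = [t for t in bundle.stim_trains
                  if not t.sham and t.frequency == 100.0 and t.amplitude == 80.0
                  and t.channel == 100]
        assert len(trains) == SMALL.icms_repetitions
        assert sum(t.pulse_times.size for t in trains) == 4 * 100

    def test_sham_trains_have_zero_amplitude_and_matched_pulses(self):
        bundle, _ = make_rest_icms_session(SMALL, seed=0)
        shams = [t for t in bundle.stim_trains if t.sham]
        assert shams and all(t.amplitude == 0.0 for t in shams)
        reals = [t for t in bundle.stim_trains if not t.sham]
        assert len(shams) == len(reals)

    def test_sham_rate_matches_baseline(self):
        bundle, truth = make_rest_icms_session(SMALL, seed=1)
        unit = bundle.units[0]
        shams = [t for t in bundle.stim_trains if t.sham]
        n = sum(np.sum((unit.times >= t.onset) & (unit.times < t.onset + t.duration))
                for t in shams)
        total_t = sum(t.duration for t in shams)
        rate = n / total_t
        sem = np.sqrt(truth.baseline[0] / total_t)
        assert rate == pytest.approx(truth.baseline[0], abs=4 * sem)

    def test_phase_locked_peak_probability_matches_thinning_oracle(self):
        """Closed form: P(spike in the latency bin) ~ 1 - (1-h) exp(-lam dt)."""
        cfg = replace(SMALL, p_phase_locked=1.0, p_non_phase_locked=0.0,
                      p_inhibited=0.0, pl_hazard=0.3,
                      site_strength_range=(1.0, 1.0),
                      icms_repetitions=10)
        bundle, truth = make_rest_icms_session(cfg, seed=2)
        site, ch = 100, bundle.units[0].channel
        resp = truth.response_map[(site, ch)]
        trains = [t for t in bundle.stim_trains
                  if not t.sham and t.channel == site
                  and t.amplitude == 80.0 and t.frequency == 100.0]
        pulses = np.concatenate([t.pulse_times for t in trains])
        unit = bundle.units[0]
        lat = resp["latency_ms"]
        hits = 0
        for p in pulses:
            a = np.searchsorted(unit.times, p + lat / 1000.0 - 1e-9)
            b = np.searchsorted(unit.times, p + (lat + 1.0) / 1000.0)
            hits += (b - a) > 0
        h = cfg.pl_hazard * 1.3 * resp["gain"]   # max amp, 100 Hz > 25 Hz boost
        lam = truth.baseline[0]
        expect = 1 - (1 - h) * np.exp(-lam * 0.001)
        sd = np.sqrt(expect * (1 - expect) / pulses.size)
        assert hits / pulses.size == pytest.approx(expect, abs=4 * sd)

    def test_blanked_intervals_carry_no_spikes(self):
        bundle, _ = make_rest_icms_session(SMALL, seed=3)
        unit = bundle.units[0]
        for train in bundle.stim_trains:
            if train.sham:
                continue
            period = 1.0 / train.frequency
            rel = unit.times - train.onset
            inside = rel[(rel >= 0) & (rel < train.duration)]
            phase = np.mod(inside, period) * 1000.0
            assert not np.any(phase < 3.0 - 1e-6)
            assert not np.any(phase > period * 1000.0 - 1.0 + 1e-6)


class TestGraspIcmsSession:
    def test_blocks_evenly_split(self):
        bundle, _ = make_grasp_icms_session(SMALL, seed=0)
        table = bundle.trial_table()
        assert len(bundle.trials) == 4 * 60
        for b, g in table.groupby("block"):
            assert len(g) == 60
            assert g["stim_index"].notna().sum() == 30

    def test_icms_onset_delay_distribution(self):
        bundle, _ = make_grasp_icms_session(SMALL, seed=1)
        delays = [bundle.stim_trains[t.stim_index].onset - t.t_touch
                  for t in bundle.trials if t.stim_index is not None]
        assert 0.18 <= np.median(delays) <= 0.24
        assert max(delays) <= 0.241 and min(delays) >= 0.179

    def test_pair_site_validation(self):
        with pytest.raises(ValidationError, match="not an S1 site"):
            make_grasp_icms_session(
                SMALL, pairs={"C": {"P400": 999, "P7000": 100}}, seed=0)

    def test_day1_day2_share_units(self):
        day1, t1 = make_day1_session(SMALL, seed=5, unit_seed=5)
        day2, t2 = make_grasp_icms_session(SMALL, seed=6, unit_seed=5)
        assert t1.unit_ids == t2.unit_ids
        np.testing.assert_allclose(t1.alpha_texture, t2.alpha_texture)
        np.testing.assert_allclose(t1.baseline, t2.baseline)

    def test_force_deviation_couples_to_net_modulation(self):
        """Force deviation on stimulated trials carries the sign and rough
        magnitude of the site's net M1 rate modulation (simulation oracle)."""
        cfg = replace(SMALL, p_phase_locked=0.0, p_non_phase_locked=1.0,
                      p_inhibited=0.0, site_strength_range=(1.0, 1.0),
                      force_noise=0.005, day2_block_size=100)
        bundle, truth = make_grasp_icms_session(cfg, seed=7)
        site_of = {i: t.channel for i, t in enumerate(bundle.stim_trains)}
        for b in {t.block for t in bundle.trials}:
            trials = [t for t in bundle.trials if t.block == b]
            site = next(site_of[t.stim_index] for t in trials
                        if t.stim_index is not None)
            expected = truth.force_effect[site]
            f_stim, f_ctrl = [], []
            for t in trials:
                t0 = (bundle.stim_trains[t.stim_index].onset
                      if t.stim_index is not None else t.t_touch + 0.210)
                seg = bundle.force.slice(t0 + 0.6, t0 + 1.0)
                (f_stim if t.stim_index is not None else f_ctrl).append(seg.mean())
            dev = np.mean(f_stim) - np.mean(f_ctrl)
            assert dev == pytest.approx(expected, abs=0.25 * abs(expected) + 0.01)

    def test_zero_gain_pair_leaves_force_unchanged(self):
        cfg = replace(SMALL, p_phase_locked=0.0, p_non_phase_locked=0.0,
                      p_inhibited=0.0)
        bundle, truth = make_grasp_icms_session(cfg, seed=8)
        assert all(v == 0.0 for v in truth.net_modulation.values())
        t0s, f_stim, f_ctrl = [], [], []
        for t in bundle.trials:
            t0 = (bundle.stim_trains[t.stim_index].onset
                  if t.stim_index is not None else t.t_touch + 0.210)
            seg = bundle.force.slice(t0 + 0.3, t0 + 0.7)
            (f_stim if t.stim_index is not None else f_ctrl).append(seg.mean())
        assert np.mean(f_stim) == pytest.approx(np.mean(f_ctrl), abs=0.02)
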