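"""Multitaper spectra, Wilson factorization and conditional Granger causality
validated against analytic and regression-based oracles."""

import numpy as np
import pytest

from cortexlink import (
    FactorizationError,
    SessionBundle,
    SpikeTrain,
    conditional_gc,
    count_session_pairs,
    multitaper_csd,
    select_top_units,
    wilson_factorize,
)
from cortexlink.cgc import cgc_pca
from cortexlink.spectral import CrossSpectrum


def var_spectrum(A_list, Sigma, T):
    """Analytic spectrum and transfer function of a VAR process on the rfft
    grid of length-T windows."""
    n = Sigma.shape[0]
    freqs = np.fft.rfftfreq(T)
    S = np.empty((freqs.size, n, n), complex)
    H = np.empty_like(S)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f)
        Az = np.eye(n, dtype=complex)
        for lag, A in enumerate(A_list, start=1):
            Az -= A * z ** lag
        Hf = np.linalg.inv(Az)
        H[i] = Hf
        S[i] = Hf @ Sigma @ Hf.conj().T
    return CrossSpectrum(frequencies=freqs, S=S, n_tapers=1, n_trials=1, fs=1.0), H


def simulate_var(A_list, Sigma, T, n_trials, rng, burn=50):
    n = Sigma.shape[0]
    L = np.linalg.cholesky(Sigma)
    p = len(A_list)
    X = np.zeros((n_trials, n, T + burn))
    e = rng.standard_normal((n_trials, n, T + burn))
    for t in range(p, T + burn):
        acc = (L @ e[:, :, t].T).T
        for lag, A in enumerate(A_list, start=1):
            acc = acc + (A @ X[:, :, t - lag].T).T
        X[:, :, t] = acc
    return X[:, :, burn:]


A1 = np.array([[0.4, 0.35, 0.2], [0.0, 0.5, 0.3], [0.0, 0.0, 0.5]])
A2 = np.array([[-0.2, 0.0, 0.0], [0.0, -0.1, 0.0], [0.0, 0.0, -0.2]])
SIGMA = np.diag([1.0, 0.9, 1.1])


def parametric_geweke(X_long, target, predictors_reduced, predictors_full, p=6):
    """Independent oracle: time-domain conditional GC from OLS residual
    variances of reduced vs full lagged regressions."""
    def resvar(target, predictors):
        T = X_long.shape[1]
        Z = np.vstack([X_long[predictors, p - lag:T - lag] for lag in range(1, p + 1)]).T
        y = X_long[target, p:]
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return float(np.var(y - Z @ beta))
    return np.log(resvar(target, predictors_reduced)
                  / resvar(target, predictors_full))


class TestMultitaper:
    def test_independent_channels_low_coherence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 2, 256))
        csd = multitaper_csd(x, fs=1.0)
        coh = (np.abs(csd.S[:, 0, 1]) ** 2
               / (csd.S[:, 0, 0].real * csd.S[:, 1, 1].real))
        assert np.mean(coh) < 0.05

    def test_channel_vs_itself_coherence_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 1, 128))
        both = np.concatenate([x, x], axis=1)
        csd = multitaper_csd(both, fs=1.0)
        coh = (np.abs(csd.S[:, 0, 1]) ** 2
               / (csd.S[:, 0, 0].real * csd.S[:, 1, 1].real))
        np.testing.assert_allclose(coh, 1.0, atol=1e-9)

    def test_cosine_modulated_rate_peaks_at_modulation_frequency(self):
        rng = np.random.default_rng(2)
        fs, T, f0 = 1000.0, 300, 40.0
        t = np.arange(T) / fs
        lam = 30.0 * (1.0 + 0.9 * np.cos(2 * np.pi * f0 * t))
        counts = (rng.random((300, 1, T)) < lam / fs).astype(float)
        csd = multitaper_csd(counts, fs=fs)
        power = csd.S[:, 0, 0].real
        mask = csd.frequencies > 10.0   # skip the DC/evoked shoulder
        peak = csd.frequencies[mask][np.argmax(power[mask])]
        assert abs(peak - f0) <= 2 * csd.frequencies[1]

    def test_degenerate_flag_for_silence(self):
        csd = multitaper_csd(np.zeros((4, 2, 100)), fs=1000.0)
        assert csd.degenerate

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            multitaper_csd(np.zeros((1, 2, 100)))


class TestWilson:
    def test_white_noise_closed_form(self):
        Sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        nf = 65
        S = np.broadcast_to(Sigma.astype(complex), (nf, 2, 2)).copy()
        csd = CrossSpectrum(np.linspace(0, 0.5, nf), S, 1, 1, 1.0)
        fact = wilson_factorize(csd)
        np.testing.assert_allclose(fact.Sigma, Sigma, atol=1e-8)
        np.testing.assert_allclose(fact.H, np.broadcast_to(np.eye(2), (nf, 2, 2)),
                                   atol=1e-7)

    def test_var_transfer_function_recovered(self):
        csd, H_true = var_spectrum([A1, A2], SIGMA, 256)
        fact = wilson_factorize(csd, tol=1e-12, max_iter=200)
        assert fact.residual < 1e-6
        np.testing.assert_allclose(fact.Sigma, SIGMA, atol=1e-6)
        np.testing.assert_allclose(fact.H, H_true, atol=1e-6)

    def test_reconstruction_residual_on_estimated_spectrum(self):
        rng = np.random.default_rng(3)
        X = simulate_var([A1, A2], SIGMA, 300, 100, rng)
        fact = wilson_factorize(multitaper_csd(X, fs=1.0))
        assert fact.residual < 1e-6
        recon = fact.reconstruct()
        S = multitaper_csd(X, fs=1.0).S
        assert np.max(np.abs(recon - S)) / np.max(np.abs(S)) < 1e-6

    def test_rank_deficient_spectrum_fails(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((20, 1, 128))
        both = np.concatenate([x, x], axis=1)     # perfectly dependent
        csd = multitaper_csd(both, fs=1.0)
        with pytest.raises(FactorizationError):
            wilson_factorize(csd)


class TestConditionalGC:
    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((150, 3, 256))
        csd = multitaper_csd(x, fs=1.0)
        scalar, _ = conditional_gc(csd, 0, 1, (2,))
        assert scalar < 0.01

    def test_matches_parametric_geweke_within_15pct(self):
        rng = np.random.default_rng(6)
        X_long = simulate_var([A1, A2], SIGMA, 200_000, 1, rng)[0]
        oracle = parametric_geweke(X_long, 0, [0, 2], [0, 1, 2])
        X = simulate_var([A1, A2], SIGMA, 300, 200, rng)
        csd = multitaper_csd(X, fs=1.0, n_tapers=3)
        est, _ = conditional_gc(csd, 0, 1, (2,))
        assert est == pytest.approx(oracle, rel=0.15)

    def test_null_direction_stays_small(self):
        rng = np.random.default_rng(7)
        X_long = simulate_var([A1, A2], SIGMA, 200_000, 1, rng)[0]
        oracle = parametric_geweke(X_long, 0, [0, 2], [0, 1, 2])
        X = simulate_var([A1, A2], SIGMA, 300, 200, rng)
        csd = multitaper_csd(X, fs=1.0)
        null, _ = conditional_gc(csd, 1, 0, (2,))   # x -> y|z is absent
        assert null < 0.1 * oracle

    def test_chain_is_suppressed_by_conditioning(self):
        # x -> y -> z: conditioning on y removes most of the x -> z influence
        A = np.zeros((3, 3))
        A[1, 0] = 0.6   # y <- x
        A[2, 1] = 0.6   # z <- y
        np.fill_diagonal(A, 0.4)
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(5):
            X = simulate_var([A], np.eye(3), 300, 150, rng)
            csd = multitaper_csd(X, fs=1.0)
            biv, _ = conditional_gc(csd, 2, 0, ())
            cond, _ = conditional_gc(csd, 2, 0, (1,))
            ratios.append(cond / max(biv, 1e-12))
        assert np.mean(ratios) <= 0.2

    def test_nonnegative_and_overlap_rejected(self):
        rng = np.random.default_rng(9)
        X = simulate_var([A1, A2], SIGMA, 256, 50, rng)
        csd = multitaper_csd(X, fs=1.0)
        scalar, spectrum = conditional_gc(csd, 0, 1, (2,))
        assert scalar >= -1e-10
        assert np.all(spectrum >= -1e-12)
        with pytest.raises(ValueError, match="distinct"):
            conditional_gc(csd, 0, 1, (1,))


class TestSelection:
    def _bundle(self, rates):
        units = [SpikeTrain(f"S1A_{i:02d}", 100 + i, "S1A",
                            np.sort(np.random.default_rng(i).uniform(0, 100, int(r * 100))))
                 for i, r in enumerate(rates)]
        return SessionBundle("s", "a", {100 + i: "S1A" for i in range(len(rates))},
                             trials=[], units=units)

    def test_top_units_by_rate(self):
        b = self._bundle(np.arange(1.0, 13.0))   # 12 distinct rates
        sel = select_top_units(b, "S1", 10)
        assert len(sel) == 10
        assert sel[0].unit_id == "S1A_11"
        assert all(sel[i].mean_rate(b.duration) >= sel[i + 1].mean_rate(b.duration)
                   for i in range(9))

    def test_fewer_units_all_returned(self):
        b = self._bundle([5.0] * 9)
        assert len(select_top_units(b, "S1", 10)) == 9

    def test_tie_breaks_lexicographically(self):
        b = self._bundle([5.0, 5.0])
        # identical generation seeds differ; force identical spike counts
        n = min(u.n_spikes for u in b.units)
        for u in b.units:
            u.times = u.times[:n]
        sel = select_top_units(b, "S1", 1)
        assert sel[0].unit_id == "S1A_00"

    def test_empty_region_raises(self):
        b = self._bundle([5.0])
        with pytest.raises(ValueError):
            select_top_units(b, "M1")

    def test_pair_enumeration_matches_study_counts(self):
        assert count_session_pairs([(12, 15)] * 16, top=10) == 1600
        assert count_session_pairs([(10, 10)] * 7 + [(9, 9)], top=10) == 781


class TestCGCPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(10)
        base = rng.random(9 * 25)
        series = (np.outer(rng.random(8) + 0.5, base)).reshape(8, 9, 25)
        pca = cgc_pca(series, components=(1, 2))
        assert pca.explained_variance[0] > 0.999
        assert pca.explained_variance[1] < 1e-6

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(11)
        series = rng.random((10, 9, 25))
        pca = cgc_pca(series)
        ev = pca.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_sign_convention(self):
        rng = np.random.default_rng(12)
        series = rng.random((6, 9, 5))
        pca = cgc_pca(series, components=(1, 2))
        for row in pca.loadings:
            assert row[np.argmax(np.abs(row))] >= 0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            cgc_pca(np.random.default_rng(0).random((2, 9, 5)), components=(3, 4))
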