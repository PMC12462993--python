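"""Multitaper cross-spectra of binned spike trains and Wilson spectral
matrix factorization.

The nonparametric route to Granger causality: estimate the cross-spectral
density (CSD) matrix of 1 ms binned, per-trial mean-subtracted spike counts
with Slepian tapers, then factor S(f) = H(f) Sigma H*(f) with Wilson's
iterative algorithm, yielding a causal transfer function H and innovation
covariance Sigma without fitting an autoregressive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky
from scipy.signal.windows import dpss

__all__ = [
    "CrossSpectrum",
    "Factorization",
    "FactorizationError",
    "multitaper_csd",
    "wilson_factorize",
]


class FactorizationError(RuntimeError):
    """Wilson iteration failed; carries residual and iteration count."""

    def __init__(self, message: str, residual: float = np.nan, iterations: int = 0):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class CrossSpectrum:
    frequencies: np.ndarray      # Hz, 0..Nyquist inclusive
    S: np.ndarray                # (n_freqs, n, n) complex Hermitian
    n_tapers: int
    n_trials: int
    fs: float
    degenerate: bool = False     # no spikes anywhere in the window

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]


@dataclass
class Factorization:
    H: np.ndarray                # (n_freqs, n, n) causal transfer function
    Sigma: np.ndarray            # (n, n) innovation covariance, SPD
    iterations: int
    residual: float              # max relative reconstruction error over f

    def reconstruct(self) -> np.ndarray:
        return np.einsum("fij,jk,flk->fil", self.H, self.Sigma, self.H.conj())


def multitaper_csd(
    counts: np.ndarray,
    fs: float = 1000.0,
    n_tapers: int = 3,
    nw: float = 2.0,
) -> CrossSpectrum:
    """Trial- and taper-averaged cross-spectral density of binned counts.

    Parameters
    ----------
    counts : (n_trials, n_channels, n_samples) spike counts (1 ms bins).
    fs : sampling rate of the binning (Hz).
    n_tapers, nw : Slepian taper count and time-bandwidth product.

    Counts are mean-subtracted per trial and channel before tapering.  The
    frequency grid runs from 0 to the Nyquist rate at ``fs / n_samples``
    resolution.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("counts must be (n_trials, n_channels, n_samples)")
    n_trials, n_ch, T = counts.shape
    if n_trials < 2:
        raise ValueError("multitaper_csd needs >= 2 trials")
    degenerate = not np.any(counts)
    x = counts - counts.mean(axis=2, keepdims=True)
    tapers = dpss(T, nw, Kmax=n_tapers)                      # (K, T)
    nf = T // 2 + 1
    S = np.zeros((nf, n_ch, n_ch), dtype=complex)
    for k in range(n_tapers):
        X = np.fft.rfft(x * tapers[k], axis=2)               # (trials, ch, nf)
        S += np.einsum("taf,tbf->fab", X, X.conj())
    S /= (n_tapers * n_trials * fs)
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    return CrossSpectrum(frequencies=freqs, S=S, n_tapers=n_tapers,
                         n_trials=n_trials, fs=fs, degenerate=degenerate)


def _full_grid(S: np.ndarray) -> np.ndarray:
    """Extend a one-sided (0..Nyquist) spectrum to the full FFT grid using
    S(-f) = S(f)^T (conjugate of a Hermitian matrix)."""
    nf = S.shape[0]
    N = 2 * (nf - 1)
    Sfull = np.empty((N,) + S.shape[1:], dtype=complex)
    Sfull[:nf] = S
    Sfull[nf:] = np.transpose(S[1:-1], (0, 2, 1))[::-1]
    return Sfull


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part [g]_+ : keep positive lags, halve the zero lag (keeping
    its upper triangle, Wilson's normalization) and the shared Nyquist lag,
    zero the negative lags."""
    N = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    gam[0] = np.triu(0.5 * gam[0])
    gam[N // 2] *= 0.5
    gam[N // 2 + 1:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    csd: CrossSpectrum | np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
    check_tol: float = 1e-6,
) -> Factorization:
    """Wilson's iterative spectral matrix factorization.

    Converges when the relative update of the spectral factor falls below
    ``tol``; raises :class:`FactorizationError` (carrying residual and
    iteration count) if the iteration does not converge or the spectrum is
    numerically rank deficient.
    """
    S = csd.S if isinstance(csd, CrossSpectrum) else np.asarray(csd, dtype=complex)
    if S.ndim != 3 or S.shape[1] != S.shape[2]:
        raise ValueError("spectrum must be (n_freqs, n, n)")
    nf, n, _ = S.shape
    Sfull = _full_grid(S)
    N = Sfull.shape[0]

    gam = np.fft.ifft(Sfull, axis=0).real
    try:
        h0 = cholesky(gam[0])            # upper triangular, h0^T h0 = gam[0]
    except np.linalg.LinAlgError as exc:
        raise FactorizationError(f"zero-lag covariance not SPD: {exc}") from exc
    psi = np.broadcast_to(h0.astype(complex), (N, n, n)).copy()

    eye = np.eye(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            inv_psi = np.linalg.inv(psi)
        except np.linalg.LinAlgError as exc:
            raise FactorizationError(
                f"singular spectral factor at iteration {it}", iterations=it
            ) from exc
        g = inv_psi @ Sfull @ np.conj(np.transpose(inv_psi, (0, 2, 1))) + eye
        psi_new = psi @ _plus_operator(g)
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break

    recon = psi @ np.conj(np.transpose(psi, (0, 2, 1)))
    scale = max(np.max(np.abs(Sfull)), 1e-300)
    residual = float(np.max(np.abs(recon - Sfull)) / scale)
    if not converged and residual > check_tol:
        raise FactorizationError(
            f"Wilson factorization did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual=residual, iterations=it,
        )

    A0 = np.fft.ifft(psi, axis=0)[0].real
    try:
        A0_inv = np.linalg.inv(A0)
    except np.linalg.LinAlgError as exc:
        raise FactorizationError("zero-lag factor singular", residual=residual,
                                 iterations=it) from exc
    Sigma = A0 @ A0.T
    H = psi[:nf] @ A0_inv
    return Factorization(H=H, Sigma=Sigma, iterations=it, residual=residual)
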