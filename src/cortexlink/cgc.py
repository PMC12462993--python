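"""Conditional Granger causality between S1 and M1 spike trains.

The directed influence from unit j to unit i conditional on an ensemble k is
computed nonparametrically: multitaper cross-spectra of 1 ms binned counts
are factorized (Wilson) for the full system (i, j, k) and the reduced system
(i, k), and the Geweke conditional measure is obtained by the
partition-matrix (variable transformation) method,

    F_{j->i|k}(f) = ln[ Sigma^{(i,k)}_ii / ( Q_ii(f) Sigma^{(i,j,k)}_ii Q*_ii(f) ) ]

where Q(f) = G_ext(f)^{-1} H~(f), G_ext embeds the reduced-system transfer
function, and H~ is the full-system transfer function after normalizing the
innovations so that unit i's noise is uncorrelated with the rest.  The
time-domain scalar reported per window is the arithmetic mean of the
spectral measure over the frequency grid (discrete Geweke integral);
negative spectral values, which arise only from factorization noise, are
floored at zero.

Significance uses a spike-jitter null: every spike is independently jittered
uniformly within +/-10 ms (within trial, re-windowed afterwards), the stage
CGC is recomputed 30 times, and the observed value must exceed the 95th
percentile of the surrogate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import SessionBundle, SpikeTrain, TrialRecord, WindowGrid, align_spikes
from .spectral import CrossSpectrum, FactorizationError, multitaper_csd, wilson_factorize
from .synth import stream
from .tuning import AnovaEffects, anova2_eta

__all__ = [
    "CGC_STAGE_T",
    "CGC_STAGE_GH",
    "CGCResult",
    "JitterNull",
    "CGCPCA",
    "select_top_units",
    "count_session_pairs",
    "conditional_gc",
    "cgc_from_counts",
    "ensemble_counts",
    "sliding_cgc",
    "stage_cgc_from_rasters",
    "jitter_null_from_rasters",
    "jitter_significance",
    "resample_condition_anova",
    "cgc_pca",
]

# Stage windows for CGC match the 300 ms analysis window length.
CGC_STAGE_T = (-100.0, 200.0)
CGC_STAGE_GH = (300.0, 600.0)


# ----------------------------------------------------------------- selection

def select_top_units(bundle: SessionBundle, region: str, n: int = 10) -> list[SpikeTrain]:
    """Top-``n`` units of a region by session-mean firing rate.

    ``region`` matches by prefix, so ``"S1"`` covers both S1 arrays.  Ties
    are broken toward the lexicographically smaller unit id so selection is
    deterministic.
    """
    units = [u for u in bundle.units if u.region.startswith(region)]
    if not units:
        raise ValueError(f"no units in region {region!r}")
    duration = bundle.duration
    ranked = sorted(units, key=lambda u: (-u.mean_rate(duration), u.unit_id))
    return ranked[: min(n, len(ranked))]


def count_session_pairs(counts: list[tuple[int, int]], top: int = 10) -> int:
    """Number of directed source x target pairs over sessions, selecting at
    most ``top`` units per region per session."""
    return int(sum(min(top, a) * min(top, b) for a, b in counts))


# ------------------------------------------------------------------ core CGC

def conditional_gc(
    csd: CrossSpectrum,
    i: int,
    j: int,
    k: tuple[int, ...] = (),
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[float, np.ndarray]:
    """Spectral and time-domain conditional GC from channel j to channel i
    given channels k, all indices into ``csd``.

    Returns ``(scalar, spectrum)`` where the scalar is the mean of the
    spectral measure over the frequency grid.
    """
    k = tuple(k)
    if len({i, j, *k}) != 2 + len(k):
        raise ValueError("i, j and k must be distinct channels")
    full_idx = [i, j, *k]
    red_idx = [i, *k]
    S = csd.S
    S_full = S[:, full_idx][:, :, full_idx]
    S_red = S[:, red_idx][:, :, red_idx]

    fact_full = wilson_factorize(S_full, tol=tol, max_iter=max_iter)
    fact_red = wilson_factorize(S_red, tol=tol, max_iter=max_iter)

    m = len(full_idx)
    Sigma = fact_full.Sigma
    H = fact_full.H
    # normalize innovations: make unit i's noise uncorrelated with the rest
    P_inv = np.eye(m)
    P_inv[1:, 0] = Sigma[1:, 0] / Sigma[0, 0]
    H_t = H @ P_inv

    nf = H.shape[0]
    G_ext = np.broadcast_to(np.eye(m, dtype=complex), (nf, m, m)).copy()
    red_pos = np.array([0] + list(range(2, m)))
    G_ext[:, red_pos[:, None], red_pos[None, :]] = fact_red.H
    Q = np.linalg.solve(G_ext, H_t)

    num = fact_red.Sigma[0, 0]
    den = np.abs(Q[:, 0, 0]) ** 2 * Sigma[0, 0]
    spectrum = np.log(np.maximum(num, 1e-300) / np.maximum(den, 1e-300))
    spectrum = np.maximum(spectrum, 0.0)
    return float(spectrum.mean()), spectrum


def cgc_from_counts(
    counts: np.ndarray,
    i: int,
    j: int,
    k: tuple[int, ...] = (),
    fs: float = 1000.0,
    n_tapers: int = 3,
) -> float:
    """Scalar conditional GC for one analysis window of binned counts
    ``(n_trials, n_channels, n_samples)``; NaN for degenerate windows."""
    csd = multitaper_csd(counts, fs=fs, n_tapers=n_tapers)
    if csd.degenerate:
        return float("nan")
    try:
        scalar, _ = conditional_gc(csd, i, j, k)
    except FactorizationError:
        return float("nan")
    return scalar


# ------------------------------------------------------------- window counts

def ensemble_counts(
    bundle: SessionBundle,
    units: list[SpikeTrain],
    trials: list[TrialRecord],
    window: tuple[float, float],
    event: str = "touch",
    bin_ms: float = 1.0,
) -> np.ndarray:
    """(n_trials, n_units, n_bins) spike counts in an event-aligned window."""
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_ms))
    out = np.zeros((len(trials), len(units), n_bins))
    edges = lo + np.arange(n_bins + 1) * bin_ms
    for ui, unit in enumerate(units):
        raster = align_spikes(unit, trials, event=event, span=(lo, hi))
        for ti, rel in enumerate(raster):
            if rel.size:
                out[ti, ui], _ = np.histogram(rel, bins=edges)
    return out


# -------------------------------------------------------------- sliding CGC

@dataclass
class CGCResult:
    source: str
    target: str
    direction: str                        # "S1->M1|M1" or "M1->S1|S1"
    conditioning: tuple[str, ...]
    window_starts: np.ndarray             # ms
    values: np.ndarray                    # nats; NaN where degenerate
    condition: tuple | None = None        # (texture, load) cell, if restricted


def _ensembles(bundle: SessionBundle, direction: str, n_top: int,
               cond_cap: int | None):
    """Selected source/target unit lists and the conditioning pool for a
    direction.  Conditioning is drawn from the *target* region's remaining
    selected units."""
    s1 = select_top_units(bundle, "S1", n_top)
    m1 = select_top_units(bundle, "M1", n_top)
    if direction in ("s1m1", "S1->M1|M1"):
        sources, targets, pool, label = s1, m1, m1, "S1->M1|M1"
    elif direction in ("m1s1", "M1->S1|S1"):
        sources, targets, pool, label = m1, s1, s1, "M1->S1|S1"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return sources, targets, pool, label, cond_cap


def _conditioning(target: SpikeTrain, source: SpikeTrain, pool: list[SpikeTrain],
                  cap: int | None) -> list[SpikeTrain]:
    others = [u for u in pool if u.unit_id not in (target.unit_id, source.unit_id)]
    return others if cap is None else others[:cap]


def sliding_cgc(
    bundle: SessionBundle,
    pairs: list[tuple[str, str]] | None = None,
    direction: str = "s1m1",
    grid: WindowGrid | None = None,
    trials: list[TrialRecord] | None = None,
    condition: tuple | None = None,
    n_top: int = 10,
    cond_cap: int | None = None,
    event: str = "touch",
    n_tapers: int = 3,
) -> list[CGCResult]:
    """Windowed conditional GC for directed unit pairs.

    ``pairs`` is a list of (source unit id, target unit id); when omitted,
    all source x target combinations of the top-``n_top`` selections are
    used.  ``condition`` restricts trials to one (texture, load) cell.
    Windows whose spectra are degenerate are emitted as NaN.
    """
    grid = grid or WindowGrid.cgc_default()
    sources, targets, pool, label, cap = _ensembles(bundle, direction, n_top, cond_cap)
    by_id = {u.unit_id: u for u in bundle.units}
    if pairs is None:
        pairs = [(s.unit_id, t.unit_id) for s in sources for t in targets]
    if trials is None:
        trials = bundle.trials
    if condition is not None:
        tex, load = condition
        trials = [t for t in trials if t.texture == tex and t.load == load]

    results = []
    for src_id, tgt_id in pairs:
        src, tgt = by_id[src_id], by_id[tgt_id]
        cond_units = _conditioning(tgt, src, pool, cap)
        system = [tgt, src] + cond_units
        k = tuple(range(2, len(system)))
        values = np.full(grid.n_windows, np.nan)
        for w, start in enumerate(grid.starts):
            X = ensemble_counts(bundle, system, trials,
                                (start, start + grid.width), event=event)
            values[w] = cgc_from_counts(X, 0, 1, k, n_tapers=n_tapers)
        results.append(CGCResult(
            source=src_id, target=tgt_id, direction=label,
            conditioning=tuple(u.unit_id for u in cond_units),
            window_starts=grid.starts.copy(), values=values,
            condition=condition))
    return results


# -------------------------------------------------------------- jitter null

@dataclass
class JitterNull:
    observed: float
    surrogates: np.ndarray
    percentile: float            # the null's pct-th percentile
    significant: bool
    n_surrogates: int
    halfwidth_ms: float


def stage_cgc_from_rasters(rasters: list[list[np.ndarray]], window: tuple[float, float],
                           n_tapers: int = 3) -> float:
    """Scalar conditional GC for one stage window from per-unit aligned
    rasters (ms); unit 0 is the target, unit 1 the source, the rest the
    conditioning set."""
    lo, hi = window
    n_bins = int(round(hi - lo))
    edges = lo + np.arange(n_bins + 1)
    n_trials = len(rasters[0])
    X = np.zeros((n_trials, len(rasters), n_bins))
    for ui, raster in enumerate(rasters):
        for ti, rel in enumerate(raster):
            sel = rel[(rel >= lo) & (rel < hi)]
            if sel.size:
                X[ti, ui], _ = np.histogram(sel, bins=edges)
    k = tuple(range(2, len(rasters)))
    return cgc_from_counts(X, 0, 1, k, n_tapers=n_tapers)


def jitter_null_from_rasters(
    rasters: list[list[np.ndarray]],
    stage: tuple[float, float],
    n_surrogates: int = 30,
    halfwidth_ms: float = 10.0,
    pct: float = 95.0,
    rng: np.random.Generator | None = None,
    n_tapers: int = 3,
) -> JitterNull:
    """Spike-jitter null from aligned rasters (spanning at least the stage
    window padded by the jitter half-width on both sides)."""
    rng = rng or np.random.default_rng(0)
    observed = stage_cgc_from_rasters(rasters, stage, n_tapers)
    surrogates = np.empty(n_surrogates)
    for s in range(n_surrogates):
        jittered = [
            [rel + rng.uniform(-halfwidth_ms, halfwidth_ms, rel.size)
             for rel in raster]
            for raster in rasters
        ]
        surrogates[s] = stage_cgc_from_rasters(jittered, stage, n_tapers)
    finite = surrogates[~np.isnan(surrogates)]
    # next-higher order statistic: the conventional (conservative) surrogate
    # percentile at small n
    threshold = float(np.percentile(finite, pct, method="higher")) \
        if finite.size else float("nan")
    significant = bool(np.isfinite(observed) and np.isfinite(threshold)
                       and observed > threshold)
    return JitterNull(observed=float(observed), surrogates=surrogates,
                      percentile=threshold, significant=significant,
                      n_surrogates=n_surrogates, halfwidth_ms=halfwidth_ms)


def jitter_significance(
    bundle: SessionBundle,
    pair: tuple[str, str],
    stage: tuple[float, float] = CGC_STAGE_GH,
    direction: str = "s1m1",
    trials: list[TrialRecord] | None = None,
    n_surrogates: int = 30,
    halfwidth_ms: float = 10.0,
    pct: float = 95.0,
    seed: int = 0,
    n_top: int = 10,
    cond_cap: int | None = None,
    event: str = "touch",
    n_tapers: int = 3,
) -> JitterNull:
    """Spike-jitter significance test for one directed pair in one stage.

    Each surrogate independently jitters every spike of every unit in the
    system uniformly within ``+/-halfwidth_ms`` (within trial), re-windows,
    and recomputes the stage CGC.  The observed value is significant iff it
    strictly exceeds the ``pct``-th percentile of the surrogate values.
    """
    sources, targets, pool, label, cap = _ensembles(bundle, direction, n_top, cond_cap)
    by_id = {u.unit_id: u for u in bundle.units}
    src, tgt = by_id[pair[0]], by_id[pair[1]]
    cond_units = _conditioning(tgt, src, pool, cap)
    system = [tgt, src] + cond_units
    if trials is None:
        trials = bundle.trials

    lo, hi = stage
    pad = halfwidth_ms
    rasters = [align_spikes(u, trials, event=event, span=(lo - pad, hi + pad))
               for u in system]
    rng = stream(seed, "jitter", pair[0], pair[1], int(lo))
    return jitter_null_from_rasters(rasters, stage, n_surrogates=n_surrogates,
                                    halfwidth_ms=halfwidth_ms, pct=pct, rng=rng,
                                    n_tapers=n_tapers)


# -------------------------------------------- trial-resampling condition ANOVA

def resample_condition_anova(
    bundle: SessionBundle,
    pair: tuple[str, str],
    direction: str = "s1m1",
    stages: dict[str, tuple[float, float]] | None = None,
    frac: float = 0.2,
    n_resamples: int = 20,
    seed: int = 0,
    n_top: int = 10,
    cond_cap: int | None = None,
    n_tapers: int = 3,
) -> dict[str, AnovaEffects]:
    """Texture x load ANOVA on trial-resampled stage CGC values.

    Per condition cell, ``n_resamples`` draws of ``round(frac * n_trials)``
    trials with replacement each yield one stage-CGC value; the two-way
    ANOVA treats resamples as replicates (reproducing the original
    procedure, pseudo-replication included).
    """
    stages = stages or {"T": CGC_STAGE_T, "GH": CGC_STAGE_GH}
    sources, targets, pool, label, cap = _ensembles(bundle, direction, n_top, cond_cap)
    by_id = {u.unit_id: u for u in bundle.units}
    src, tgt = by_id[pair[0]], by_id[pair[1]]
    cond_units = _conditioning(tgt, src, pool, cap)
    system = [tgt, src] + cond_units

    cells: dict[tuple, list[TrialRecord]] = {}
    for t in bundle.trials:
        cells.setdefault((t.texture, t.load), []).append(t)
    for cell, ts in cells.items():
        if len(ts) < 5:
            raise ValueError(f"condition cell {cell} has fewer than 5 trials")

    rng = stream(seed, "resample", pair[0], pair[1])
    lo = min(s[0] for s in stages.values())
    hi = max(s[1] for s in stages.values())
    rasters_by_cell = {
        cell: [align_spikes(u, ts, span=(lo, hi)) for u in system]
        for cell, ts in cells.items()
    }

    records: dict[str, list[float]] = {name: [] for name in stages}
    tex_labels, load_labels = [], []
    for cell, ts in cells.items():
        n_draw = max(int(round(frac * len(ts))), 2)
        rasters = rasters_by_cell[cell]
        for _ in range(n_resamples):
            take = rng.integers(0, len(ts), n_draw)
            sub = [[raster[t] for t in take] for raster in rasters]
            for name, window in stages.items():
                records[name].append(stage_cgc_from_rasters(sub, window, n_tapers))
            tex_labels.append(cell[0])
            load_labels.append(cell[1])

    out = {}
    for name in stages:
        vals = np.array(records[name])
        vals = np.where(np.isnan(vals), 0.0, vals)
        out[name] = anova2_eta(vals, np.array(tex_labels), np.array(load_labels))
    return out


# ------------------------------------------------------------------------ PCA

@dataclass
class CGCPCA:
    loadings: np.ndarray            # (n_components, n_features)
    explained_variance: np.ndarray  # fractions, nonincreasing
    scores: np.ndarray              # (n_pairs, n_components)
    projections: np.ndarray | None  # resampled CGC onto requested components
    components: tuple[int, ...]
    mean: np.ndarray = field(repr=False, default=None)


def cgc_pca(
    series: np.ndarray,
    resampled: np.ndarray | None = None,
    components: tuple[int, ...] = (3, 4),
) -> CGCPCA:
    """PCA of per-pair CGC trajectories concatenated over the nine tactile
    conditions.

    Parameters
    ----------
    series : (n_pairs, n_conditions, n_windows) window CGC values.
    resampled : optional (n_samples, n_conditions, n_windows) resampled CGC
        feature vectors to project onto the requested (1-based) components.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3:
        raise ValueError("series must be (n_pairs, n_conditions, n_windows)")
    n_pairs = series.shape[0]
    X = np.nan_to_num(series.reshape(n_pairs, -1))
    if n_pairs < max(components):
        raise ValueError("fewer pairs than requested components")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: each component's largest-magnitude loading is positive
    for c in range(Vt.shape[0]):
        imax = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, imax] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    var = s ** 2
    total = float(np.sum((X - X.mean(axis=0)) ** 2)) or 1.0
    explained = var / total
    scores = U * s
    projections = None
    if resampled is not None:
        R = np.nan_to_num(np.asarray(resampled, dtype=float).reshape(
            resampled.shape[0], -1))
        cols = [c - 1 for c in components]
        projections = (R - mean) @ Vt[cols].T
    return CGCPCA(loadings=Vt, explained_variance=explained, scores=scores,
                  projections=projections, components=components, mean=mean)
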