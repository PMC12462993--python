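"""Windowed two-way ANOVA effect decomposition and unit inclusion rules.

For every analysis window the trial-wise firing rate of a unit is decomposed
by a two-way ANOVA over texture and load, and each factor's effect size is
the eta-squared fraction

    eta2_i = SS_i / (SS_texture + SS_load + SS_texture_x_load + SS_error)

computed with Type-II sums of squares (Type I and II coincide on the
balanced default design).  Sliding this over a 200 ms window with a 50 ms
step yields per-unit effect time series; units with fewer than five
significant windows for both texture and load on the tuning grid are
classified as tactilely insensitive.  The Bonferroni-style threshold is
``alpha / (n_factors * n_windows / n_inclusion)``, which for the default
grid (3 factors, 23 windows, 5 inclusion windows) gives 0.0036.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import SpikeTrain, TrialRecord, WindowGrid, align_spikes, window_counts

__all__ = [
    "AnovaEffects",
    "EffectSeries",
    "StageDefinition",
    "UnitTuningSummary",
    "STAGE_T",
    "STAGE_GH",
    "anova2_eta",
    "effect_series",
    "corrected_threshold",
    "include_unit",
    "stage_windows",
    "stage_mean",
    "stage_compare",
]

FACTORS = ("texture", "load", "interaction")

STAGE_T = None   # populated below once StageDefinition exists
STAGE_GH = None


@dataclass
class AnovaEffects:
    eta: dict[str, float]       # factor -> eta^2 in [0, 1]
    p: dict[str, float]         # factor -> p-value from the F distribution
    degenerate: bool = False    # total SS == 0 (e.g. constant responses)


@dataclass
class StageDefinition:
    label: str
    span: tuple[float, float]   # ms relative to alignment event


STAGE_T = StageDefinition("T", (-50.0, 150.0))
STAGE_GH = StageDefinition("GH", (350.0, 550.0))


@dataclass
class EffectSeries:
    unit_id: str
    grid: WindowGrid
    eta: dict[str, np.ndarray]        # factor -> (n_windows,)
    p: dict[str, np.ndarray]
    degenerate: np.ndarray            # bool per window


@dataclass
class UnitTuningSummary:
    unit_id: str
    included: bool
    n_sig: dict[str, int]             # significant-window counts per factor
    peak_latency: dict[str, float]    # window start (ms) of argmax eta^2
    stage_eta: dict[str, dict[str, float]]   # stage label -> factor -> mean eta^2


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, idx = np.unique(labels, return_inverse=True)
    return np.eye(len(levels))[idx], levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova2_eta(values, texture, load) -> AnovaEffects:
    """Two-way fixed-effects ANOVA effect decomposition for one window.

    Parameters
    ----------
    values : (n_trials,) responses (window firing rates).
    texture, load : (n_trials,) factor labels.

    Returns eta^2 and p per factor using Type-II sums of squares.  If the
    total sum of squares is zero the result is all-zero with the degenerate
    flag set.  Raises ``ValueError`` naming the first empty design cell.
    """
    y = np.asarray(values, dtype=float)
    tex = np.asarray(texture)
    lod = np.asarray(load)
    A, a_levels = _one_hot(tex)
    B, b_levels = _one_hot(lod)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("anova2_eta requires >= 2 levels per factor")
    for ta in a_levels:
        for lb in b_levels:
            if not np.any((tex == ta) & (lod == lb)):
                raise ValueError(f"empty design cell (texture={ta!r}, load={lb!r})")
    n = y.size
    if n <= a * b:
        raise ValueError("anova2_eta requires >= 2 trials per cell")

    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0.0:
        zero = {f: 0.0 for f in FACTORS}
        return AnovaEffects(eta=dict(zero), p={f: 1.0 for f in FACTORS}, degenerate=True)

    ones = np.ones((n, 1))
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, a * b)
    X_a = np.hstack([ones, A[:, 1:]])
    X_b = np.hstack([ones, B[:, 1:]])
    X_ab = np.hstack([ones, A[:, 1:], B[:, 1:]])
    X_full = AB  # cell-means parameterization spans the full model

    rss_a = _rss(X_a, y)
    rss_b = _rss(X_b, y)
    rss_ab = _rss(X_ab, y)
    rss_full = _rss(X_full, y)

    # Type-II: each main effect adjusted for the other; interaction last.
    ss = {
        "texture": max(rss_b - rss_ab, 0.0),
        "load": max(rss_a - rss_ab, 0.0),
        "interaction": max(rss_ab - rss_full, 0.0),
    }
    ss_err = rss_full
    df = {"texture": a - 1, "load": b - 1, "interaction": (a - 1) * (b - 1)}
    df_err = n - a * b

    denom = ss["texture"] + ss["load"] + ss["interaction"] + ss_err
    eta = {f: (ss[f] / denom if denom > 0 else 0.0) for f in FACTORS}
    p = {}
    for f in FACTORS:
        if ss_err <= 0.0:
            p[f] = 0.0 if ss[f] > 0 else 1.0
            continue
        F = (ss[f] / df[f]) / (ss_err / df_err)
        p[f] = float(stats.f.sf(F, df[f], df_err))
    return AnovaEffects(eta=eta, p=p, degenerate=False)


def effect_series(
    unit: SpikeTrain,
    trials: list[TrialRecord],
    grid: WindowGrid | None = None,
    event: str = "touch",
) -> EffectSeries:
    """Per-window ANOVA effect decomposition for one unit (Hz rates)."""
    grid = grid or WindowGrid.tuning_default()
    raster = align_spikes(unit, trials, event=event, span=grid.span)
    rates = window_counts(raster, grid)
    tex = np.array([t.texture for t in trials])
    lod = np.array([t.load for t in trials])
    eta = {f: np.zeros(grid.n_windows) for f in FACTORS}
    p = {f: np.ones(grid.n_windows) for f in FACTORS}
    degenerate = np.zeros(grid.n_windows, dtype=bool)
    for w in range(grid.n_windows):
        res = anova2_eta(rates[:, w], tex, lod)
        degenerate[w] = res.degenerate
        for f in FACTORS:
            eta[f][w] = res.eta[f]
            p[f][w] = res.p[f]
    return EffectSeries(unit_id=unit.unit_id, grid=grid, eta=eta, p=p,
                        degenerate=degenerate)


def corrected_threshold(alpha: float = 0.05, n_factors: int = 3,
                        n_windows: int = 23, n_inclusion: int = 5) -> float:
    """Corrected significance threshold ``alpha / (n_factors * n_windows /
    n_inclusion)``, reported to 4 decimals (default grid: 0.0036)."""
    if min(alpha, n_factors, n_windows, n_inclusion) <= 0:
        raise ValueError("all inputs must be positive")
    return round(alpha / (n_factors * n_windows / n_inclusion), 4)


def stage_windows(grid: WindowGrid, stage: StageDefinition) -> np.ndarray:
    """Boolean mask of windows fully contained in the stage span."""
    lo, hi = stage.span
    return (grid.starts >= lo - 1e-9) & (grid.starts + grid.width <= hi + 1e-9)


def stage_mean(series: EffectSeries, stage: StageDefinition, factor: str) -> float:
    mask = stage_windows(series.grid, stage)
    if not mask.any():
        return float("nan")
    return float(series.eta[factor][mask].mean())


def include_unit(series: EffectSeries, threshold: float | None = None,
                 min_windows: int = 5,
                 stages: tuple[StageDefinition, ...] = (STAGE_T, STAGE_GH),
                 ) -> UnitTuningSummary:
    """Tactile-sensitivity inclusion rule.

    A unit is included iff it has at least ``min_windows`` significant
    windows for texture *or* for load on the tuning grid (units failing both
    are tactilely insensitive); the interaction factor does not count.
    """
    if threshold is None:
        threshold = corrected_threshold(n_windows=series.grid.n_windows,
                                        n_inclusion=min_windows)
    n_sig = {f: int(np.sum(series.p[f] < threshold)) for f in FACTORS}
    included = n_sig["texture"] >= min_windows or n_sig["load"] >= min_windows
    peak = {f: float(series.grid.starts[int(np.argmax(series.eta[f]))])
            for f in FACTORS}
    stage_eta = {s.label: {f: stage_mean(series, s, f) for f in FACTORS}
                 for s in stages}
    return UnitTuningSummary(unit_id=series.unit_id, included=included,
                             n_sig=n_sig, peak_latency=peak, stage_eta=stage_eta)


@dataclass
class StageCompareReport:
    factor: str
    stage_a: str
    stage_b: str
    n: int
    statistic: float
    p: float
    direction: int    # sign of median(stage_a - stage_b)


def stage_compare(series_set: list[EffectSeries], stage_a: StageDefinition,
                  stage_b: StageDefinition, factor: str,
                  alternative: str = "two-sided") -> StageCompareReport:
    """Paired Wilcoxon signed-rank test on per-unit stage-mean eta^2."""
    if len(series_set) < 2:
        raise ValueError("stage_compare needs at least 2 units")
    xa = np.array([stage_mean(s, stage_a, factor) for s in series_set])
    xb = np.array([stage_mean(s, stage_b, factor) for s in series_set])
    diff = xa - xb
    direction = int(np.sign(np.median(diff)))
    if np.allclose(diff, 0.0):
        return StageCompareReport(factor, stage_a.label, stage_b.label,
                                  len(diff), 0.0, 1.0, 0)
    stat, p = stats.wilcoxon(xa, xb, alternative=alternative,
                             correction=True, method="auto")
    return StageCompareReport(factor, stage_a.label, stage_b.label,
                              len(diff), float(stat), float(p), direction)
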