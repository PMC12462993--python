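"""Day-2 modulation analyses: artifact-blanked windowed decoding and the
normalized indices of ICMS effect.

All time courses run on 200 ms windows stepped by 40 ms, aligned to the
stimulation-train onset (control trials use the nominal onset, touch plus
the session's median trigger delay, so blanking and windowing are identical
with and without stimulation).  Within the 1 s train, the first 3 ms and
the last 1 ms of every 10 ms stimulation cycle are blanked as artifacts for
training and testing data alike; window rates are corrected for the blanked
time.

Indices:

* ``I_ACC(t) = (ACC_ICMS - ACC_NONE) / ACC_NONE`` — relative change in
  tactile classification accuracy of a decoder trained on day-1 trials.
* ``Bias(t) = (F_decoded - F_real) / F_real`` from a linear support-vector
  regression of grip force on M1 features; the decoding-bias index is
  ``Bias_ICMS - Bias_NONE`` (the bias is already normalized by the real
  force).
* ``I_F(t) = (F_ICMS - F_NONE) / F_NONE`` — relative grip-force deviation.
* ``I_N(t)`` — cross-validated accuracy of classifying stimulated vs
  control trials; chance (0.5) means no detectable neural intervention.

Stage summaries use GRASP (0-280 ms) and HOLD (400-680 ms) after train
onset; the headline correlation windows are I_N in 140-500 ms and I_F in
200-700 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .decoding import cv_accuracy, svm_pipeline
from .session import SessionBundle, SpikeTrain, TrialRecord, WindowGrid, align_spikes
from .tuning import anova2_eta

__all__ = [
    "STAGE_GRASP",
    "STAGE_HOLD",
    "IN_WINDOW",
    "IF_WINDOW",
    "IndexSeries",
    "index_grid",
    "nominal_onsets",
    "blanked_features",
    "tactile_channels",
    "iacc_series",
    "force_decode_bias",
    "i_f_series",
    "i_n_series",
    "in_if_correlation",
    "adaptation_check",
    "interaction_test",
]

STAGE_GRASP = (0.0, 280.0)
STAGE_HOLD = (400.0, 680.0)
IN_WINDOW = (140.0, 500.0)
IF_WINDOW = (200.0, 700.0)

TRAIN_MS = 1000.0
CYCLE_MS = 10.0
BLANK_POST_MS = 3.0
BLANK_PRE_MS = 1.0


def index_grid(first: float = -500.0, last: float = 1300.0,
               width: float = 200.0, step: float = 40.0) -> WindowGrid:
    """Default index window grid: 200 ms / 40 ms over -500..1500 ms."""
    return WindowGrid.regular(first, last, width, step)


def _contained(grid: WindowGrid, span: tuple[float, float]) -> np.ndarray:
    lo, hi = span
    return (grid.starts >= lo - 1e-9) & (grid.starts + grid.width <= hi + 1e-9)


@dataclass
class IndexSeries:
    kind: str                       # "I_ACC", "BiasDelta", "I_F", "I_N"
    window_starts: np.ndarray       # ms relative to stimulation onset
    values: np.ndarray              # NaN where undefined
    label: str = ""                 # pair / block / condition tag
    stage_means: dict[str, float] = field(default_factory=dict)

    def window_mean(self, span: tuple[float, float]) -> float:
        grid = WindowGrid(width=200.0, step=40.0, starts=self.window_starts)
        mask = _contained(grid, span)
        vals = self.values[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def _stage_means(starts: np.ndarray, values: np.ndarray,
                 width: float = 200.0) -> dict[str, float]:
    out = {}
    for name, span in (("GRASP", STAGE_GRASP), ("HOLD", STAGE_HOLD)):
        mask = (starts >= span[0] - 1e-9) & (starts + width <= span[1] + 1e-9)
        vals = values[mask]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out


# ----------------------------------------------------------------- alignment

def nominal_onsets(bundle: SessionBundle,
                   trials: list[TrialRecord] | None = None) -> np.ndarray:
    """Per-trial stimulation-onset times (s).  Control trials fall back to
    touch + the session's median trigger delay, so blanking keys on the
    stimulation *cycle*, not on whether current was delivered."""
    trials = trials if trials is not None else bundle.trials
    delay = float(bundle.meta.get("delay_median_s", 0.210))
    out = np.empty(len(trials))
    for i, t in enumerate(trials):
        if t.stim_index is not None:
            out[i] = bundle.stim_trains[t.stim_index].onset
        else:
            out[i] = t.t_touch + delay
    return out


def _blank_mask(rel_ms: np.ndarray) -> np.ndarray:
    """True where a spike (ms relative to train onset) falls in an artifact
    interval of the stimulation cycle."""
    inside = (rel_ms >= 0) & (rel_ms < TRAIN_MS)
    phase = np.mod(rel_ms, CYCLE_MS)
    return inside & ((phase < BLANK_POST_MS) | (phase >= CYCLE_MS - BLANK_PRE_MS))


def _counted_ms(edges: np.ndarray) -> np.ndarray:
    """Non-blanked time (ms) per bin given bin edges relative to onset."""
    fine = 0.05
    out = np.empty(edges.size - 1)
    for i in range(edges.size - 1):
        t = np.arange(edges[i], edges[i + 1], fine) + fine / 2
        out[i] = fine * np.sum(~_blank_mask(t))
    return out


def blanked_features(
    bundle: SessionBundle,
    units: list[SpikeTrain],
    trials: list[TrialRecord],
    grid: WindowGrid | None = None,
    bin_ms: float = 40.0,
    apply_blanking: bool = True,
) -> np.ndarray:
    """Artifact-blanked, onset-aligned decoding features.

    Returns ``(n_windows, n_trials, n_units, n_bins)`` rates (Hz) with each
    bin's rate computed over its non-blanked time only.
    """
    grid = grid or index_grid()
    onsets = nominal_onsets(bundle, trials)
    n_bins = int(round(grid.width / bin_ms))
    span = (float(grid.starts[0]), float(grid.starts[-1] + grid.width))
    out = np.zeros((grid.n_windows, len(trials), len(units), n_bins))

    lattice = abs(grid.step - bin_ms) < 1e-9
    if lattice:
        # windows are consecutive slices of one shared bin lattice
        n_base = grid.n_windows - 1 + n_bins
        base_edges = grid.starts[0] + np.arange(n_base + 1) * bin_ms
        counted = _counted_ms(base_edges) if apply_blanking \
            else np.full(n_base, bin_ms)
        base = np.zeros((len(trials), len(units), n_base))
        for ui, unit in enumerate(units):
            raster = align_spikes(unit, trials, span=span, times=onsets)
            for ti, rel in enumerate(raster):
                if apply_blanking and rel.size:
                    rel = rel[~_blank_mask(rel)]
                if rel.size:
                    base[ti, ui], _ = np.histogram(rel, bins=base_edges)
        rates = np.where(counted > 0, base / (counted / 1000.0), 0.0)
        for w in range(grid.n_windows):
            out[w] = rates[:, :, w:w + n_bins]
        return out

    counted = {}
    for w, start in enumerate(grid.starts):
        edges = start + np.arange(n_bins + 1) * bin_ms
        key = round(float(start), 6)
        counted[key] = _counted_ms(edges) if apply_blanking \
            else np.full(n_bins, bin_ms)
    for ui, unit in enumerate(units):
        raster = align_spikes(unit, trials, span=span, times=onsets)
        for ti, rel in enumerate(raster):
            if apply_blanking and rel.size:
                rel = rel[~_blank_mask(rel)]
            if not rel.size:
                continue
            for w, start in enumerate(grid.starts):
                edges = start + np.arange(n_bins + 1) * bin_ms
                counts, _ = np.histogram(rel, bins=edges)
                ct = counted[round(float(start), 6)]
                out[w, ti, ui] = np.where(ct > 0, counts / (ct / 1000.0), 0.0)
    return out


def tactile_channels(bundle: SessionBundle, window: tuple[float, float] = (0.0, 500.0),
                     alpha: float = 0.05) -> list[str]:
    """M1 units with a significant tactile main effect on mean rates in
    ``window`` after touch (one-way F test across the two levels)."""
    labels = np.array([t.texture for t in bundle.trials])
    levels = list(dict.fromkeys(labels))
    keep = []
    for unit in bundle.units_in("M1"):
        raster = align_spikes(unit, bundle.trials, span=window)
        rates = np.array([r.size for r in raster], dtype=float)
        groups = [rates[labels == lvl] for lvl in levels]
        if any(np.var(g) > 0 for g in groups):
            _, p = stats.f_oneway(*groups)
            if p < alpha:
                keep.append(unit.unit_id)
    return keep


# -------------------------------------------------------------------- blocks

def block_info(bundle: SessionBundle) -> list[dict]:
    """Block metadata (id, tactile level, pair label) recorded by the
    generator, or reconstructed from the trial table."""
    if "blocks" in bundle.meta:
        return list(bundle.meta["blocks"])
    out = []
    for b in sorted({t.block for t in bundle.trials}):
        lvl = next(t.texture for t in bundle.trials if t.block == b)
        out.append({"block": b, "level": lvl, "pair": ""})
    return out


def _block_trials(bundle: SessionBundle, block: int) -> list[TrialRecord]:
    return [t for t in bundle.trials if t.block == block]


# ------------------------------------------------------------------- I_ACC

def iacc_series(
    day1: SessionBundle,
    day2: SessionBundle,
    pair: str,
    grid: WindowGrid | None = None,
    channels: list[str] | None = None,
    scope: str = "single",
    alpha: float = 0.05,
    bin_ms: float = 40.0,
) -> IndexSeries:
    """Relative tactile-classification accuracy change under one stimulus
    pair: decoder trained per window on day-1 (no-ICMS) trials, tested on
    day-2 stimulated vs control trials of that pair's blocks.

    ``scope="single"`` trains one decoder per tactile-sensitive channel and
    averages the per-channel index (the headline index); ``"population"``
    trains one decoder on all those channels jointly.  Windows where a
    control accuracy is zero are emitted as NaN.
    """
    grid = grid or index_grid()
    if channels is None:
        channels = tactile_channels(day1, alpha=alpha)
    units1 = [u for u in day1.units if u.unit_id in channels]
    units2 = [u for u in day2.units if u.unit_id in channels]
    if not units1 or len(units1) != len(units2):
        raise ValueError("no shared tactile-sensitive channels between days")

    blocks = [b["block"] for b in block_info(day2) if b["pair"] == pair]
    trials2 = [t for t in day2.trials if t.block in blocks]
    y1 = np.array([t.texture for t in day1.trials])
    y2 = np.array([t.texture for t in trials2])
    stim = np.array([t.stim_index is not None for t in trials2])

    X1 = blanked_features(day1, units1, day1.trials, grid, bin_ms=bin_ms)
    X2 = blanked_features(day2, units2, trials2, grid, bin_ms=bin_ms)

    groups = ([np.arange(len(units1))] if scope == "population"
              else [np.array([i]) for i in range(len(units1))])
    values = np.full(grid.n_windows, np.nan)
    for w in range(grid.n_windows):
        vals = []
        for g in groups:
            clf = svm_pipeline()
            clf.fit(X1[w][:, g, :].reshape(len(y1), -1), y1)
            pred = clf.predict(X2[w][:, g, :].reshape(len(y2), -1))
            acc_icms = float(np.mean(pred[stim] == y2[stim]))
            acc_none = float(np.mean(pred[~stim] == y2[~stim]))
            if acc_none > 0:
                vals.append((acc_icms - acc_none) / acc_none)
        if vals:
            values[w] = float(np.mean(vals))
    return IndexSeries(kind="I_ACC", window_starts=grid.starts.copy(),
                       values=values, label=pair,
                       stage_means=_stage_means(grid.starts, values, grid.width))


# ------------------------------------------------------------- force decoding

def _force_window_means(bundle: SessionBundle, trials: list[TrialRecord],
                        grid: WindowGrid) -> np.ndarray:
    """(n_trials, n_windows) mean grip force per window, onset-aligned."""
    onsets = nominal_onsets(bundle, trials)
    out = np.empty((len(trials), grid.n_windows))
    for ti, t0 in enumerate(onsets):
        for w, start in enumerate(grid.starts):
            seg = bundle.force.slice(t0 + start / 1000.0,
                                     t0 + (start + grid.width) / 1000.0)
            out[ti, w] = seg.mean() if seg.size else np.nan
    return out


def _svr_pipeline() -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("svr", SVR(kernel="linear", C=1.0))])


def force_decode_bias(
    day1: SessionBundle,
    day2: SessionBundle,
    pair: str,
    grid: WindowGrid | None = None,
    bin_ms: float = 40.0,
    floor_frac: float = 0.05,
) -> dict[str, IndexSeries]:
    """Grip-force decoding bias under one stimulus pair, per tactile level.

    A linear-kernel SVR is trained per window on day-1 M1 features against
    the window-mean grip force, then applied to day-2 trials.  Returns, per
    tactile level, the decoding-bias index ``Bias_ICMS(t) - Bias_NONE(t)``
    where ``Bias = (F_decoded - F_real)/F_real``; windows with the real
    force under ``floor_frac`` of the peak condition mean are NaN.
    """
    grid = grid or index_grid()
    units1 = day1.units_in("M1")
    ids = [u.unit_id for u in units1]
    units2 = [u for u in day2.units if u.unit_id in ids]

    X1 = blanked_features(day1, units1, day1.trials, grid, bin_ms=bin_ms)
    F1 = _force_window_means(day1, day1.trials, grid)

    blocks = [b["block"] for b in block_info(day2) if b["pair"] == pair]
    trials2 = [t for t in day2.trials if t.block in blocks]
    X2 = blanked_features(day2, units2, trials2, grid, bin_ms=bin_ms)
    F2 = _force_window_means(day2, trials2, grid)
    stim = np.array([t.stim_index is not None for t in trials2])
    levels = list(dict.fromkeys(t.texture for t in trials2))
    lvl_of = np.array([t.texture for t in trials2])

    floor = floor_frac * np.nanmax(np.abs(F2))
    out: dict[str, IndexSeries] = {}
    bias2 = np.full(F2.shape, np.nan)
    for w in range(grid.n_windows):
        ok1 = np.isfinite(F1[:, w])
        model = _svr_pipeline()
        model.fit(X1[w][ok1].reshape(ok1.sum(), -1), F1[ok1, w])
        pred = model.predict(X2[w].reshape(len(trials2), -1))
        real = F2[:, w]
        good = np.isfinite(real) & (np.abs(real) >= floor)
        bias2[good, w] = (pred[good] - real[good]) / real[good]
    for lvl in levels:
        sel = lvl_of == lvl
        vals = (np.nanmean(bias2[sel & stim], axis=0)
                - np.nanmean(bias2[sel & ~stim], axis=0))
        out[lvl] = IndexSeries(kind="BiasDelta", window_starts=grid.starts.copy(),
                               values=vals, label=f"{pair}:{lvl}",
                               stage_means=_stage_means(grid.starts, vals,
                                                        grid.width))
    return out


# ------------------------------------------------------------------ I_F, I_N

def i_f_series(bundle: SessionBundle, block: int,
               grid: WindowGrid | None = None,
               floor_frac: float = 0.05) -> IndexSeries:
    """Relative grip-force deviation of stimulated vs control trials in one
    block; the block summary is the mean over 300-700 ms after onset."""
    grid = grid or index_grid()
    trials = _block_trials(bundle, block)
    stim = np.array([t.stim_index is not None for t in trials])
    if not stim.any() or stim.all():
        raise ValueError(f"block {block} lacks stimulated or control trials")
    F = _force_window_means(bundle, trials, grid)
    f_icms = np.nanmean(F[stim], axis=0)
    f_none = np.nanmean(F[~stim], axis=0)
    floor = floor_frac * np.nanmax(np.abs(f_none))
    values = np.where(np.abs(f_none) >= floor,
                      (f_icms - f_none) / f_none, np.nan)
    series = IndexSeries(kind="I_F", window_starts=grid.starts.copy(),
                         values=values, label=f"block{block}",
                         stage_means=_stage_means(grid.starts, values, grid.width))
    series.stage_means["300-700"] = series.window_mean((300.0, 700.0))
    return series


def i_n_series(bundle: SessionBundle, block: int,
               grid: WindowGrid | None = None,
               folds: int = 5, seed: int = 0,
               bin_ms: float = 40.0) -> IndexSeries:
    """Windowed cross-validated accuracy of classifying stimulated vs
    control trials on blanked M1 features (the neural-modulation index)."""
    grid = grid or index_grid()
    trials = _block_trials(bundle, block)
    y = np.array(["icms" if t.stim_index is not None else "none" for t in trials])
    if len(set(y)) < 2:
        raise ValueError(f"block {block} lacks stimulated or control trials")
    X = blanked_features(bundle, bundle.units_in("M1"), trials, grid, bin_ms=bin_ms)
    values = np.array([cv_accuracy(X[w].reshape(len(y), -1), y,
                                   folds=folds, seed=seed)
                       for w in range(grid.n_windows)])
    series = IndexSeries(kind="I_N", window_starts=grid.starts.copy(),
                         values=values, label=f"block{block}",
                         stage_means=_stage_means(grid.starts, values, grid.width))
    series.stage_means["140-500"] = series.window_mean(IN_WINDOW)
    return series


# -------------------------------------------------------------- correlation

@dataclass
class CorrelationReport:
    r: float
    p: float
    n_blocks: int
    in_window: tuple[float, float]
    if_window: tuple[float, float]
    matrix: np.ndarray | None = None     # cross-window correlation (I_N x I_F)
    window_starts: np.ndarray | None = None


def in_if_correlation(
    in_series: list[IndexSeries],
    if_series: list[IndexSeries],
    in_window: tuple[float, float] = IN_WINDOW,
    if_window: tuple[float, float] = IF_WINDOW,
    full_matrix: bool = True,
) -> CorrelationReport:
    """Pearson correlation between block-level mean I_N and mean I_F at the
    headline windows, plus the full cross-window correlation matrix."""
    if len(in_series) != len(if_series) or len(in_series) < 5:
        raise ValueError("need >= 5 matched (I_N, I_F) block series")
    x = np.array([s.window_mean(in_window) for s in in_series])
    y = np.array([s.window_mean(if_window) for s in if_series])
    if np.allclose(np.var(x), 0) or np.allclose(np.var(y), 0):
        raise ValueError("zero-variance index values across blocks")
    r, p = stats.pearsonr(x, y)
    matrix = None
    starts = in_series[0].window_starts
    if full_matrix:
        A = np.stack([s.values for s in in_series])      # (blocks, windows)
        B = np.stack([s.values for s in if_series])
        nw = A.shape[1]
        matrix = np.full((nw, nw), np.nan)
        for i in range(nw):
            for j in range(nw):
                a, b = A[:, i], B[:, j]
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 3 and np.var(a[ok]) > 0 and np.var(b[ok]) > 0:
                    matrix[i, j] = stats.pearsonr(a[ok], b[ok])[0]
    return CorrelationReport(r=float(r), p=float(p), n_blocks=len(x),
                             in_window=in_window, if_window=if_window,
                             matrix=matrix, window_starts=starts)


# --------------------------------------------------------------- adaptation

@dataclass
class AdaptationReport:
    kind: str
    positions: np.ndarray
    values: np.ndarray          # mean index per stimulated-trial position
    rho: float
    p: float


def adaptation_check(bundle: SessionBundle, kind: str = "I_F",
                     window: tuple[float, float] = (300.0, 700.0),
                     folds: int = 5, seed: int = 0) -> AdaptationReport:
    """Index as a function of stimulated-trial position within blocks, with
    a Spearman trend test (adaptation would show a monotone decline)."""
    grid = WindowGrid.regular(window[0], window[0], window[1] - window[0], 1.0)
    blocks = sorted({t.block for t in bundle.trials})
    per_block = []
    for b in blocks:
        trials = _block_trials(bundle, b)
        stim_trials = [t for t in trials if t.stim_index is not None]
        ctrl_trials = [t for t in trials if t.stim_index is None]
        if len(stim_trials) < 2:
            raise ValueError(f"block {b} has fewer than 2 stimulated trials")
        if kind == "I_F":
            f_stim = _force_window_means(bundle, stim_trials, grid)[:, 0]
            f_none = float(np.nanmean(
                _force_window_means(bundle, ctrl_trials, grid)[:, 0]))
            per_block.append((f_stim - f_none) / f_none)
        elif kind == "I_N":
            y = np.array(["icms" if t.stim_index is not None else "none"
                          for t in trials])
            X = blanked_features(bundle, bundle.units_in("M1"), trials,
                                 WindowGrid(width=window[1] - window[0], step=1.0,
                                            starts=np.array([window[0]])))
            Xw = X[0].reshape(len(y), -1)
            correct = np.zeros(len(y))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for train, test in skf.split(Xw, y):
                clf = svm_pipeline()
                clf.fit(Xw[train], y[train])
                correct[test] = clf.predict(Xw[test]) == y[test]
            stim_mask = y == "icms"
            per_block.append(correct[stim_mask])
        else:
            raise ValueError(f"unknown index kind {kind!r}")
    n_pos = min(len(v) for v in per_block)
    M = np.stack([v[:n_pos] for v in per_block])
    values = M.mean(axis=0)
    positions = np.arange(1, n_pos + 1)
    rho, p = stats.spearmanr(positions, values)
    return AdaptationReport(kind=kind, positions=positions, values=values,
                            rho=float(rho), p=float(p))


# -------------------------------------------------- stimulation x tactile

@dataclass
class InteractionReport:
    channels: list[str]
    p_interaction: np.ndarray
    flagged: list[str]
    consistent: np.ndarray        # per flagged channel, mean accuracy
    inconsistent: np.ndarray
    p_contrast: float


def interaction_test(
    bundle: SessionBundle,
    window: tuple[float, float] = (0.0, 400.0),
    alpha: float = 0.05,
    folds: int = 5,
    seed: int = 0,
    grid: WindowGrid | None = None,
    bin_ms: float = 40.0,
) -> InteractionReport:
    """Stimulation-site x tactile-level interaction on M1 rates, and the
    cross-level site-classification contrast for interacting channels.

    On stimulated trials, a two-way ANOVA of the 0-400 ms mean rate flags
    channels with a site x level interaction (p < ``alpha``).  For each
    flagged channel a site classifier is cross-validated within one tactile
    level and tested on both; accuracy on the training level (consistent)
    is compared to the other level (inconsistent) by paired Wilcoxon.
    """
    stim_trials = [t for t in bundle.trials if t.stim_index is not None]
    sites = np.array([bundle.stim_trains[t.stim_index].channel for t in stim_trials])
    levels = np.array([t.texture for t in stim_trials])
    if len(set(sites)) < 2 or len(set(levels)) < 2:
        raise ValueError("need 2 stimulation sites x 2 tactile levels")

    m1 = bundle.units_in("M1")
    onsets = nominal_onsets(bundle, stim_trials)
    p_int = np.empty(len(m1))
    for ui, unit in enumerate(m1):
        raster = align_spikes(unit, stim_trials, span=window, times=onsets)
        rates = np.array([r.size for r in raster], dtype=float)
        res = anova2_eta(rates, sites, levels)
        p_int[ui] = res.p["interaction"]
    flagged_idx = [i for i in range(len(m1)) if p_int[i] < alpha]
    flagged = [m1[i].unit_id for i in flagged_idx]

    grid = grid or WindowGrid.regular(window[0], window[1] - 200.0, 200.0, 40.0)
    lvl_names = list(dict.fromkeys(levels))
    cons, incons = [], []
    X = blanked_features(bundle, m1, stim_trials, grid, bin_ms=bin_ms)
    for i in flagged_idx:
        acc_c, acc_i = [], []
        for w in range(grid.n_windows):
            Xi = X[w, :, i, :]
            m_t1 = levels == lvl_names[0]
            y_site = sites.astype(str)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            c_fold, i_fold = [], []
            X_t1, y_t1 = Xi[m_t1], y_site[m_t1]
            X_t2, y_t2 = Xi[~m_t1], y_site[~m_t1]
            for train, test in skf.split(X_t1, y_t1):
                clf = svm_pipeline()
                clf.fit(X_t1[train], y_t1[train])
                c_fold.append(np.mean(clf.predict(X_t1[test]) == y_t1[test]))
                i_fold.append(np.mean(clf.predict(X_t2) == y_t2))
            acc_c.append(np.mean(c_fold))
            acc_i.append(np.mean(i_fold))
        cons.append(np.mean(acc_c))
        incons.append(np.mean(acc_i))
    cons, incons = np.array(cons), np.array(incons)
    if len(cons) >= 2 and not np.allclose(cons, incons):
        _, p_contrast = stats.wilcoxon(cons, incons)
    else:
        p_contrast = 1.0
    return InteractionReport(channels=[u.unit_id for u in m1],
                             p_interaction=p_int, flagged=flagged,
                             consistent=cons, inconsistent=incons,
                             p_contrast=float(p_contrast))
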