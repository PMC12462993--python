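"""Population and single-channel tactile decoding.

The decoder is a fixed contract, not a contribution: a Gaussian-kernel
max-margin classifier (SVC, C = 1.0, kernel scale 1/(d * var)) on per-unit
binned firing rates (4 x 50 ms bins per 200 ms window by default), features
standardized on training folds only, assessed by stratified k-fold
cross-validation with a seeded shuffle reused across windows so time
courses are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .session import SpikeTrain, TrialRecord, WindowGrid, align_spikes

__all__ = [
    "DroppingCurve",
    "svm_pipeline",
    "feature_tensor",
    "classify_tactile",
    "cv_accuracy",
    "dropping_curve",
]


def svm_pipeline() -> Pipeline:
    """Standardize-then-SVC pipeline with the fixed, documented
    hyperparameters (regularization 1.0, kernel scale 1/(d * variance))."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=1.0, gamma="scale")),
    ])


def feature_tensor(
    units: list[SpikeTrain],
    trials: list[TrialRecord],
    grid: WindowGrid | None = None,
    bin_ms: float = 50.0,
    event: str = "touch",
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Per-window decoding features.

    Returns ``(n_windows, n_trials, n_units, n_bins)`` binned rates (Hz),
    where ``n_bins = window_width / bin_ms``.  Flatten the last two axes for
    a classifier input.
    """
    grid = grid or WindowGrid.tuning_default()
    n_bins = int(round(grid.width / bin_ms))
    span = (float(grid.starts[0]), float(grid.starts[-1] + grid.width))
    n_trials = len(trials)
    out = np.zeros((grid.n_windows, n_trials, len(units), n_bins))
    for ui, unit in enumerate(units):
        raster = align_spikes(unit, trials, event=event, span=span, times=times)
        for ti, rel in enumerate(raster):
            if not rel.size:
                continue
            for w, start in enumerate(grid.starts):
                edges = start + np.arange(n_bins + 1) * bin_ms
                out[w, ti, ui], _ = np.histogram(rel, bins=edges)
    return out / (bin_ms / 1000.0)


def cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int = 10,
                seed: int = 0) -> float:
    """Stratified k-fold cross-validated accuracy of the fixed SVC contract."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} trials, "
            f"fewer than {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        clf = svm_pipeline()
        clf.fit(X[train], y[train])
        correct += int(np.sum(clf.predict(X[test]) == y[test]))
    return correct / len(y)


def classify_tactile(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated decoding accuracy per window.

    ``features`` is ``(n_windows, n_trials, ...)``; trailing axes are
    flattened per trial.  The same seeded fold split is reused across
    windows.
    """
    features = np.asarray(features, dtype=float)
    n_windows, n_trials = features.shape[:2]
    X_all = features.reshape(n_windows, n_trials, -1)
    return np.array([cv_accuracy(X_all[w], labels, folds=folds, seed=seed)
                     for w in range(n_windows)])


@dataclass
class DroppingCurve:
    ordering: str                 # "texture", "load", or "random"
    unit_counts: np.ndarray
    accuracy: np.ndarray          # mean accuracy per retained-unit count
    n_repeats: int = 1

    @property
    def minimal_fraction(self) -> float:
        """Smallest retained fraction reaching 95% of the curve's top
        accuracy."""
        target = 0.95 * float(np.max(self.accuracy))
        n_max = int(np.max(self.unit_counts))
        for c, a in zip(self.unit_counts, self.accuracy):
            if a >= target:
                return float(c) / n_max
        return 1.0


def dropping_curve(
    features: np.ndarray,
    labels: np.ndarray,
    orderings: dict[str, np.ndarray],
    unit_counts: list[int] | None = None,
    n_random: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, DroppingCurve]:
    """Accuracy vs retained-unit count for importance-ordered and random
    unit dropping.

    Parameters
    ----------
    features : (n_trials, n_units, n_bins) stage features.
    orderings : name -> per-unit importance score (higher = kept longer);
        a ``"random"`` entry (any value) triggers ``n_random`` seeded
        random orders averaged into one curve.
    """
    features = np.asarray(features, dtype=float)
    n_trials, n_units, _ = features.shape
    if unit_counts is None:
        unit_counts = sorted({max(1, int(round(n_units * f / 10))) for f in range(1, 11)})
    unit_counts = np.asarray(unit_counts)

    def curve_for(order: np.ndarray) -> np.ndarray:
        acc = np.empty(len(unit_counts))
        for ci, c in enumerate(unit_counts):
            keep = order[:c]
            X = features[:, keep, :].reshape(n_trials, -1)
            acc[ci] = cv_accuracy(X, labels, folds=folds, seed=seed)
        return acc

    out: dict[str, DroppingCurve] = {}
    rng = np.random.default_rng(seed)
    for name, scores in orderings.items():
        if name == "random":
            curves = []
            for _ in range(n_random):
                order = rng.permutation(n_units)
                curves.append(curve_for(order))
            out[name] = DroppingCurve(name, unit_counts,
                                      np.mean(curves, axis=0), n_repeats=n_random)
        else:
            order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
            out[name] = DroppingCurve(name, unit_counts, curve_for(order))
    return out
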