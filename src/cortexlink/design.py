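"""Stimulation-pair design from day-1 data.

The day-1 procedure: rank M1 channels by how well they discriminate the two
tactile levels, map each candidate S1 site's effect on those channels from
rest-state ICMS, and pick site-to-level assignments that either widen
(Distinguishable, D) or narrow (Confusable, C) the firing-rate gap between
levels — plus a Weak (W) pair that perturbs M1 least.  C and D use the same
two sites with swapped level assignment.

The original selection was manual; here it is an explicit score: for an
assignment {T1 -> site_a, T2 -> site_b},

    score = sum over tactile-sensitive channels of
            (FR_T1 - FR_T2) * [effect(site_a, ch) - effect(site_b, ch)]

(positive = gap-increasing).  Weighting by the signed rate difference
rather than its sign keeps channels with marginal tuning from casting full
votes and penalizes assignments that would overshoot and reverse a strong
channel's tuning.  Sites whose significant contributions are substantially
mixed in sign are avoided, and "clear firing-rate distinction" is
operationalized as a label-permutation test on single-channel decoding
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .decoding import cv_accuracy, feature_tensor
from .icms import ResponseMap
from .session import SessionBundle, WindowGrid
from .synth import stream

__all__ = [
    "TactileRanking",
    "StimPairDesign",
    "rank_tactile_channels",
    "score_pair",
    "select_pairs",
    "select_weak_pair",
]


@dataclass
class TactileRanking:
    channels: list[int]
    levels: tuple[str, str]
    accuracy: np.ndarray          # 10-fold CV accuracy per channel
    signed_diff: np.ndarray       # FR_T1 - FR_T2 (Hz) per channel
    p_perm: np.ndarray            # label-permutation p per channel
    sensitive: np.ndarray         # bool per channel

    def sensitive_channels(self) -> list[int]:
        return [c for c, s in zip(self.channels, self.sensitive) if s]


@dataclass
class StimPairDesign:
    kind: str                      # "C", "D" or "W"
    assignment: dict[str, int]     # tactile level -> S1 site channel
    score: float
    driver_channels: list[int]

    @property
    def sites(self) -> tuple[int, int]:
        return tuple(self.assignment[lvl] for lvl in sorted(self.assignment))


def rank_tactile_channels(
    bundle: SessionBundle,
    window: tuple[float, float] = (0.0, 500.0),
    bin_ms: float = 50.0,
    folds: int = 10,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> TactileRanking:
    """Rank M1 channels by single-channel tactile decoding on day-1 data.

    Features are 50 ms binned rates in 0-500 ms after touch; sensitivity is
    decided by a label-permutation test on the cross-validated accuracy
    (p < ``alpha``), the quantitative stand-in for visual PSTH inspection.
    """
    levels = tuple(bundle.texture_levels)
    if len(levels) != 2:
        raise ValueError("rank_tactile_channels expects exactly two tactile levels")
    labels = np.array([t.texture for t in bundle.trials])
    for lvl in levels:
        if int(np.sum(labels == lvl)) < 20:
            raise ValueError(f"level {lvl!r} has fewer than 20 trials")

    m1 = bundle.units_in("M1")
    lo, hi = window
    grid = WindowGrid(width=hi - lo, step=hi - lo, starts=np.array([lo]))
    feats = feature_tensor(m1, bundle.trials, grid, bin_ms=bin_ms)[0]
    # feats: (n_trials, n_channels, n_bins)
    mean_rate = feats.mean(axis=2)
    mask_t1 = labels == levels[0]
    signed = mean_rate[mask_t1].mean(axis=0) - mean_rate[~mask_t1].mean(axis=0)

    rng = stream(seed, "rank-perm")
    acc = np.empty(len(m1))
    p_perm = np.empty(len(m1))
    for ci in range(len(m1)):
        X = feats[:, ci, :]
        acc[ci] = cv_accuracy(X, labels, folds=folds, seed=seed)
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            null[p] = cv_accuracy(X, rng.permutation(labels), folds=folds, seed=seed)
        p_perm[ci] = (1 + np.sum(null >= acc[ci])) / (n_permutations + 1)
    return TactileRanking(
        channels=[u.channel for u in m1], levels=levels, accuracy=acc,
        signed_diff=signed, p_perm=p_perm, sensitive=p_perm < alpha)


def score_pair(ranking: TactileRanking, response_map: ResponseMap,
               assignment: dict[str, int]) -> float:
    """Signed gap-change score of a site-to-level assignment (positive =
    gap-increasing across tactile-sensitive channels), weighted by each
    channel's measured rate difference."""
    t1, t2 = ranking.levels
    total = 0.0
    for ch, diff, sens in zip(ranking.channels, ranking.signed_diff, ranking.sensitive):
        if not sens or diff == 0:
            continue
        total += diff * (response_map.raw_effect(assignment[t1], ch)
                         - response_map.raw_effect(assignment[t2], ch))
    return float(total)


def _admissible_sites(ranking: TactileRanking, response_map: ResponseMap,
                      sites: list[int], mixed_tolerance: float = 1 / 3) -> list[int]:
    """Drop sites whose significant contributions to sensitive channels have
    substantially mixed gap-change signs (heterogeneous effects are avoided).

    A site is excluded when the minority sign carries more than
    ``mixed_tolerance`` of the total contribution magnitude; a strictly
    single-signed profile is ideal but rarely attainable on real maps."""
    keep = []
    for s in sites:
        pos = neg = 0.0
        for ch, diff, sens in zip(ranking.channels, ranking.signed_diff,
                                  ranking.sensitive):
            if not sens or not response_map.significant(s, ch):
                continue
            g = diff * response_map.raw_effect(s, ch)
            if g > 0:
                pos += g
            elif g < 0:
                neg += -g
        total = pos + neg
        if total == 0 or min(pos, neg) / total <= mixed_tolerance:
            keep.append(s)
    return keep


def _candidate_sites(response_map: ResponseMap) -> list[int]:
    return sorted({site for site, _ in response_map.entries})


def select_pairs(ranking: TactileRanking, response_map: ResponseMap,
                 ) -> dict[str, StimPairDesign]:
    """Choose the D pair (score-maximizing assignment over admissible site
    pairs) and the C pair (same sites, swapped levels).

    Deterministic: site pairs are scanned in index order, strict improvement
    required, so ties resolve to the smallest site indices.
    """
    sites = _candidate_sites(response_map)
    if len(sites) < 2:
        raise ValueError("need at least 2 candidate sites")
    # only sites with a significant effect on at least one tactile-sensitive
    # channel can steer the representation
    sens = ranking.sensitive_channels()
    effective = [s for s in sites
                 if any(response_map.significant(s, ch) for ch in sens)]
    if len(effective) < 2:
        raise ValueError("no admissible site pair: fewer than 2 sites with a "
                         "significant effect on a tactile-sensitive channel")
    admissible = _admissible_sites(ranking, response_map, effective)
    if len(admissible) < 2:
        # mixed-sign sites "should be avoided", not banned: fall back to the
        # effective set rather than refusing a design
        warnings.warn("fewer than 2 single-signed sites; falling back to all "
                      "sites with significant effects", stacklevel=2)
        admissible = effective
    t1, t2 = ranking.levels
    drivers = ranking.sensitive_channels()
    best: StimPairDesign | None = None
    for a, b in combinations(admissible, 2):
        for asg in ({t1: a, t2: b}, {t1: b, t2: a}):
            s = score_pair(ranking, response_map, asg)
            if best is None or s > best.score:
                best = StimPairDesign(kind="D", assignment=dict(asg), score=s,
                                      driver_channels=drivers)
    swapped = {t1: best.assignment[t2], t2: best.assignment[t1]}
    c_pair = StimPairDesign(kind="C", assignment=swapped,
                            score=score_pair(ranking, response_map, swapped),
                            driver_channels=drivers)
    return {"D": best, "C": c_pair}


def select_weak_pair(response_map: ResponseMap,
                     levels: tuple[str, str] | None = None) -> StimPairDesign:
    """Pair of sites minimizing the count (then total magnitude) of
    significantly modulated M1 channels.

    ``levels`` names the tactile levels for the assignment mapping (the two
    weak sites are interchangeable; the lower-index site goes to the first
    level).
    """
    sites = _candidate_sites(response_map)
    if len(sites) < 2:
        raise ValueError("need at least 2 candidate sites")
    channels = sorted({ch for _, ch in response_map.entries})

    def cost(site: int) -> tuple[int, float]:
        n = sum(response_map.significant(site, ch) for ch in channels)
        mag = sum(abs(response_map.effect(site, ch)) for ch in channels)
        return n, mag

    ranked = sorted(sites, key=lambda s: (*cost(s), s))
    a, b = ranked[0], ranked[1]
    n_total = cost(a)[0] + cost(b)[0]
    if min(cost(s)[0] for s in sites) > 0:
        warnings.warn("all candidate sites significantly modulate M1; "
                      "returning the minimal-effect pair", stacklevel=2)
    lv = levels or ("T1", "T2")
    return StimPairDesign(kind="W", assignment={lv[0]: a, lv[1]: b},
                          score=-float(n_total), driver_channels=[])
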