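"""Synthetic session generator with ground truth.

Emulates the statistical structure of the grasping experiments so that every
analysis stage can be verified without animal data:

* **Grasp sessions** — a 3x3 texture x load design (~30 trials/condition in
  18 mirrored blocks), units whose log firing rate carries early texture
  tuning (peaking around touch), late load tuning (during grasp-and-hold),
  an optional interaction term, and directed S1->M1 coupling through short
  (3-6 ms) alpha-function kernels.
* **Rest-state ICMS sessions** — 1 s stimulation trains with 3 s gaps, 14
  repetitions per (site, amplitude, frequency) parameter set plus matched
  sham trains; M1 channels respond per a ground-truth taxonomy: phase-locked
  excitation (per-pulse hazard at a fixed 3-6 ms latency), non-phase-locked
  sustained elevation, or inhibition.
* **Day-2 grasp + ICMS sessions** — blocks of 60 trials, half stimulated
  (train onset at touch + ~210 ms), with the rest-state response gains
  superposed on task activity and a grip-force deviation from 300 ms after
  train onset proportional to the net signed M1 rate modulation, which
  couples the neural and behavioral modulation indices by construction.

Spikes are drawn from a discretized conditionally-Poisson process: Bernoulli
per 1 ms bin with ``p = 1 - exp(-lambda * dt)``, log-rate clipped at a
configured ceiling.  Pulse-locked ICMS spikes are superposed as independent
per-pulse Bernoulli events, an exact superposition of Poisson components
that keeps closed-form oracles available.

Randomness: one RNG stream per (seed, named purpose) derived through
``numpy.random.SeedSequence([seed, crc32(name)])`` so that the same (config,
seed) always yields bit-identical bundles, independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .session import (
    ForceTrace,
    SessionBundle,
    SpikeTrain,
    StimTrain,
    TrialRecord,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Edge",
    "make_grasp_session",
    "make_rest_icms_session",
    "make_grasp_icms_session",
    "make_day1_session",
    "stream",
]

BIN_S = 0.001          # 1 ms generator resolution
LOG_RATE_CEIL = np.log(400.0)   # Hz; pathological-bin guard


def stream(seed: int, *names: str | int) -> np.random.Generator:
    """Named RNG stream derived from the master seed (documented split rule)."""
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(n).encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(np.random.SeedSequence(words))


# --------------------------------------------------------------------- config

@dataclass
class Edge:
    """Directed coupling edge: source spikes add an alpha-kernel bump to the
    target's log rate after ``latency_ms``."""

    source: str
    target: str
    latency_ms: float
    gain: float
    width_ms: float = 2.0


@dataclass
class GeneratorConfig:
    # design
    trials_per_condition: int = 30          # protocol floor: 25
    texture_levels: tuple[str, ...] = ("P7000", "P400", "P36")   # smooth -> rough
    load_levels: tuple[float, ...] = (400.0, 550.0, 700.0)      # grams
    # populations
    n_m1: int = 12
    n_s1a: int = 8
    n_s1b: int = 8
    baseline_rate: float = 8.0              # Hz, lognormal across units
    baseline_spread: float = 0.35           # sigma of log baseline
    # tactile tuning (log-rate amplitudes; per-unit draw in [0.5, 1.5] x value)
    tuned_fraction: float = 0.6
    alpha_texture: float = 0.7
    alpha_load: float = 0.7
    alpha_interaction: float = 0.15
    # probability that tuning raises the rate with rougher texture / heavier
    # load (population preference is mostly consistent in direction)
    tuning_sign_bias: float = 0.9
    texture_kernel: tuple[float, float] = (50.0, 60.0)    # center, sd (ms)
    load_kernel: tuple[float, float] = (450.0, 80.0)
    interaction_kernel: tuple[float, float] = (300.0, 80.0)
    # sustained tuning carried through grasp-and-hold (fraction of peak);
    # keeps tactile information present when the ICMS train arrives
    texture_sustain: float = 0.35
    load_sustain: float = 0.35
    # S1 -> M1 coupling
    n_edges: int = 4
    edge_gain: float = 3.0
    edge_latency_range: tuple[float, float] = (3.0, 6.0)   # ms
    edge_width_ms: float = 2.0
    edge_condition_scale: float = 0.0       # gain x (1 + scale * texture code)
    # trial timing (seconds)
    reach_delay: float = 0.55
    reach_jitter: float = 0.05
    hold_duration: float = 1.5
    trial_period: float = 3.5
    # force model (arbitrary units)
    force_rate: float = 100.0               # Hz
    force_baseline: float = 0.05
    force_plateau: float = 1.0
    force_load_gain: float = 0.6            # plateau increase, min -> max load
    force_texture_gain: float = -0.25   # smoother texture (lower friction) needs more grip
    force_tau: float = 0.15                 # rise time constant, s
    force_noise: float = 0.03
    # rest-state ICMS
    n_stim_sites: int = 10
    icms_amplitudes: tuple[float, ...] = (20.0, 50.0, 80.0)   # microamperes
    icms_frequencies: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0)  # Hz
    icms_train_s: float = 1.0
    icms_gap_s: float = 3.0
    icms_repetitions: int = 14
    icms_baseline_rate: float = 40.0        # Hz, multi-unit channels
    # ground-truth response taxonomy probabilities per (site, channel)
    p_phase_locked: float = 0.12
    p_non_phase_locked: float = 0.10
    p_inhibited: float = 0.12
    pl_hazard: float = 0.30                 # per-pulse spike prob at max amplitude
    npl_gain: float = 0.30                  # sustained log-rate multiplier - 1
    inh_gain: float = 0.40                  # fractional suppression at max amplitude
    site_strength_range: tuple[float, float] = (0.05, 1.0)  # per-site heterogeneity
    freq_boost_above_hz: float = 25.0       # gains step up above this frequency
    freq_boost: float = 1.3
    # day-2 grasp + ICMS
    day2_block_size: int = 60               # half stimulated
    day2_delay_median_s: float = 0.210
    day2_delay_jitter_s: float = 0.030
    day2_amplitude: float = 80.0
    day2_frequency: float = 100.0
    force_neural_coupling: float = 0.003    # force units per Hz net M1 modulation
    blank_post_pulse_ms: float = 3.0
    blank_pre_pulse_ms: float = 1.0

    def validate(self) -> None:
        if self.trials_per_condition < 25:
            raise ValidationError("trials_per_condition must be >= 25")
        for name in ("baseline_rate", "icms_baseline_rate", "force_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.texture_levels or not self.load_levels:
            raise ValidationError("texture_levels and load_levels must be nonempty")


@dataclass
class GroundTruth:
    """Registry of generating parameters for parameter-recovery tests."""

    unit_ids: list[str] = field(default_factory=list)
    tuned: np.ndarray | None = None              # bool per unit
    alpha_texture: np.ndarray | None = None      # signed log-rate amplitude
    alpha_load: np.ndarray | None = None
    alpha_interaction: np.ndarray | None = None
    baseline: np.ndarray | None = None           # Hz
    edges: list[Edge] = field(default_factory=list)
    kernels: dict = field(default_factory=dict)
    # ICMS: (site_channel, m1_channel) -> dict(type, gain, latency_ms)
    response_map: dict = field(default_factory=dict)
    net_modulation: dict = field(default_factory=dict)   # site -> Hz (signed)
    force_effect: dict = field(default_factory=dict)
    condition_codes: dict = field(default_factory=dict)


# ------------------------------------------------------------------ internals

def _alpha_kernel(latency_ms: float, width_ms: float, n_bins: int = 40) -> np.ndarray:
    """Alpha function peaking at ``latency_ms + width_ms`` with unit peak."""
    t = np.arange(n_bins) * 1000.0 * BIN_S
    s = np.clip(t - latency_ms, 0.0, None)
    k = (s / width_ms) * np.exp(1.0 - s / width_ms)
    k[t < latency_ms] = 0.0
    return k


def _gauss(t_ms: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center) / sd) ** 2)


def _level_codes(n: int) -> np.ndarray:
    """Centered, unit-spread codes for ordered factor levels."""
    x = np.arange(n, dtype=float)
    x -= x.mean()
    if n > 1:
        x /= x.max()
    return x


def _draw_unit_params(cfg: GeneratorConfig, rng: np.random.Generator):
    regions = (["M1"] * cfg.n_m1 + ["S1A"] * cfg.n_s1a + ["S1B"] * cfg.n_s1b)
    n = len(regions)
    ids, channels = [], []
    counters = {"M1": 0, "S1A": 0, "S1B": 0}
    base_ch = {"M1": 0, "S1A": 100, "S1B": 200}
    for r in regions:
        ids.append(f"{r}_{counters[r]:02d}")
        channels.append(base_ch[r] + counters[r])
        counters[r] += 1
    base = cfg.baseline_rate * np.exp(rng.normal(0, cfg.baseline_spread, n))
    tuned = rng.random(n) < cfg.tuned_fraction
    b = cfg.tuning_sign_bias
    sign = np.stack([
        rng.choice([-1.0, 1.0], size=n, p=[1 - b, b]),
        rng.choice([-1.0, 1.0], size=n, p=[1 - b, b]),
        rng.choice([-1.0, 1.0], size=n),
    ], axis=1)
    mag = 0.5 + rng.random((n, 3))
    a_tex = np.where(tuned, cfg.alpha_texture * sign[:, 0] * mag[:, 0], 0.0)
    a_load = np.where(tuned, cfg.alpha_load * sign[:, 1] * mag[:, 1], 0.0)
    a_int = np.where(tuned, cfg.alpha_interaction * sign[:, 2] * mag[:, 2], 0.0)
    return ids, channels, regions, base, tuned, a_tex, a_load, a_int


def _default_edges(cfg: GeneratorConfig, ids: Sequence[str], regions: Sequence[str],
                   rng: np.random.Generator) -> list[Edge]:
    s1 = [u for u, r in zip(ids, regions) if r.startswith("S1")]
    m1 = [u for u, r in zip(ids, regions) if r == "M1"]
    n = min(cfg.n_edges, len(s1), len(m1))
    lo, hi = cfg.edge_latency_range
    return [
        Edge(source=s1[i], target=m1[i], latency_ms=float(rng.uniform(lo, hi)),
             gain=cfg.edge_gain, width_ms=cfg.edge_width_ms)
        for i in range(n)
    ]


def _make_trials(cfg: GeneratorConfig, rng: np.random.Generator):
    """Mirrored block design: each condition cell appears once in the first
    half of blocks and once, in reverse order, in the second half."""
    cells = list(product(cfg.texture_levels, cfg.load_levels))
    order = [cells[i] for i in rng.permutation(len(cells))]
    blocks = order + order[::-1]
    n_first = int(np.ceil(cfg.trials_per_condition / 2))
    trials: list[TrialRecord] = []
    t = 5.0
    idx = 0
    for b, (tex, load) in enumerate(blocks):
        n_b = n_first if b < len(cells) else cfg.trials_per_condition - n_first
        for _ in range(n_b):
            t_cue = t
            t_touch = t_cue + cfg.reach_delay + rng.uniform(-1, 1) * cfg.reach_jitter
            t_hold_end = t_touch + cfg.hold_duration
            trials.append(TrialRecord(index=idx, block=b, texture=tex, load=load,
                                      t_cue=t_cue, t_touch=t_touch, t_hold_end=t_hold_end))
            idx += 1
            t += cfg.trial_period
    return trials


def _sustain(t_ms: np.ndarray, center: float) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh((t_ms - center) / 150.0))


def _tuning_lograte(cfg: GeneratorConfig, t_ms: np.ndarray, base: float,
                    a_tex: float, a_load: float, a_int: float,
                    x_tex: float, x_load: float) -> np.ndarray:
    g_tex = (_gauss(t_ms, *cfg.texture_kernel)
             + cfg.texture_sustain * _sustain(t_ms, cfg.texture_kernel[0]))
    g_load = (_gauss(t_ms, *cfg.load_kernel)
              + cfg.load_sustain * _sustain(t_ms, cfg.load_kernel[0]))
    g_int = _gauss(t_ms, *cfg.interaction_kernel)
    return (np.log(base)
            + a_tex * g_tex * x_tex
            + a_load * g_load * x_load
            + a_int * g_int * x_tex * x_load)


def _sample_binary(lograte: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lam = np.exp(np.clip(lograte, None, LOG_RATE_CEIL))
    p = 1.0 - np.exp(-lam * BIN_S)
    return (rng.random(lograte.shape) < p).astype(np.uint8)


def _gap_spikes(rate: float, gaps: list[tuple[float, float]],
                rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spikes inside inter-trial gaps."""
    out = []
    for a, b in gaps:
        if b <= a:
            continue
        n = rng.poisson(rate * (b - a))
        if n:
            out.append(np.sort(rng.uniform(a, b, n)))
    return np.concatenate(out) if out else np.array([])


# ------------------------------------------------------------- grasp sessions

TRIAL_WIN = (-0.8, 1.7)    # generation window around touch, seconds


def make_grasp_session(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    session_id: str = "grasp-0",
    edges: list[Edge] | None = None,
) -> tuple[SessionBundle, GroundTruth]:
    """Generate one grasping session under the crossed texture x load design."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng_struct = stream(seed, session_id, "structure")
    rng_spk = stream(seed, session_id, "spikes")
    rng_force = stream(seed, session_id, "force")

    ids, channels, regions, base, tuned, a_tex, a_load, a_int = _draw_unit_params(cfg, rng_struct)
    if edges is None:
        edges = _default_edges(cfg, ids, regions, rng_struct)
    trials = _make_trials(cfg, rng_struct)

    tex_code = dict(zip(cfg.texture_levels, _level_codes(len(cfg.texture_levels))))
    load_code = dict(zip(cfg.load_levels, _level_codes(len(cfg.load_levels))))

    n_bins = int(round((TRIAL_WIN[1] - TRIAL_WIN[0]) / BIN_S))
    t_ms = (TRIAL_WIN[0] + np.arange(n_bins) * BIN_S) * 1000.0

    # generation order: units without incoming edges first
    targets = {e.target for e in edges}
    order = [u for u in ids if u not in targets] + [u for u in ids if u in targets]
    uidx = {u: i for i, u in enumerate(ids)}
    in_edges: dict[str, list[Edge]] = {u: [] for u in ids}
    for e in edges:
        in_edges[e.target].append(e)

    binary: dict[str, np.ndarray] = {}    # unit -> (n_trials, n_bins)
    n_trials = len(trials)
    x_tex = np.array([tex_code[t.texture] for t in trials])
    x_load = np.array([load_code[t.load] for t in trials])

    for u in order:
        i = uidx[u]
        lograte = np.empty((n_trials, n_bins))
        for k in range(n_trials):
            lograte[k] = _tuning_lograte(cfg, t_ms, base[i], a_tex[i], a_load[i],
                                         a_int[i], x_tex[k], x_load[k])
        for e in in_edges[u]:
            kern = _alpha_kernel(e.latency_ms, e.width_ms)
            src = binary[e.source].astype(float)
            gain = e.gain * (1.0 + cfg.edge_condition_scale * x_tex)[:, None]
            drive = np.empty_like(src)
            for k in range(n_trials):
                drive[k] = np.convolve(src[k], kern)[:n_bins]
            lograte += gain * drive
        binary[u] = _sample_binary(lograte, rng_spk)

    # assemble spike trains: trial-window spikes + homogeneous baseline in gaps
    touch = np.array([t.t_touch for t in trials])
    spans = [(t0 + TRIAL_WIN[0], t0 + TRIAL_WIN[1]) for t0 in touch]
    gaps = []
    prev = 0.0
    for a, b in spans:
        gaps.append((prev, a))
        prev = b
    session_end = prev + 2.0
    gaps.append((prev, session_end))

    units = []
    for u in ids:
        i = uidx[u]
        rows, cols = np.nonzero(binary[u])
        in_trial = touch[rows] + TRIAL_WIN[0] + (cols + 0.5) * BIN_S
        gap_sp = _gap_spikes(base[i], gaps, rng_spk)
        times = np.sort(np.concatenate([in_trial, gap_sp]))
        units.append(SpikeTrain(unit_id=u, channel=channels[i], region=regions[i],
                                times=times, sorted=True))

    force = _make_force(cfg, trials, session_end, x_tex, rng_force)

    bundle = SessionBundle(
        session_id=session_id, animal_id="synthetic-A",
        regions=dict(zip(channels, regions)),
        trials=trials, units=units, force=force,
        texture_levels=list(cfg.texture_levels), load_levels=list(cfg.load_levels),
        meta={"generator": "grasp", "seed": seed},
    )
    truth = GroundTruth(
        unit_ids=ids, tuned=tuned, alpha_texture=a_tex, alpha_load=a_load,
        alpha_interaction=a_int, baseline=base, edges=list(edges),
        kernels={"texture": cfg.texture_kernel, "load": cfg.load_kernel,
                 "interaction": cfg.interaction_kernel},
        condition_codes={"texture": tex_code, "load": load_code},
    )
    return bundle, truth


def _make_force(cfg: GeneratorConfig, trials, session_end, x_tex,
                rng: np.random.Generator,
                deviation: Mapping[int, tuple[float, float]] | None = None) -> ForceTrace:
    """Continuous grip-force trace: per-trial rise to a condition-dependent
    plateau plus smoothed noise.  ``deviation`` maps trial index -> (onset_s,
    signed magnitude) for ICMS-induced force shifts (ramping in over 200 ms
    from 300 ms after train onset)."""
    n = int(np.ceil(session_end * cfg.force_rate))
    t = np.arange(n) / cfg.force_rate
    load_min, load_max = min(cfg.load_levels), max(cfg.load_levels)
    span = (load_max - load_min) or 1.0
    values = np.full(n, cfg.force_baseline)
    for k, tr in enumerate(trials):
        plateau = (cfg.force_plateau
                   + cfg.force_load_gain * (tr.load - load_min) / span
                   + cfg.force_texture_gain * x_tex[k])
        i0 = int(tr.t_touch * cfg.force_rate)
        i1 = min(int((tr.t_hold_end + 0.2) * cfg.force_rate), n)
        tt = t[i0:i1] - tr.t_touch
        prof = plateau * (1.0 - np.exp(-tt / cfg.force_tau))
        if deviation and tr.index in deviation:
            onset, mag = deviation[tr.index]
            ramp = np.clip((t[i0:i1] - onset - 0.3) / 0.2, 0.0, 1.0)
            prof = prof + mag * ramp
        values[i0:i1] = cfg.force_baseline + prof
    noise = rng.normal(0, cfg.force_noise, n)
    w = max(int(0.05 * cfg.force_rate), 1)
    noise = np.convolve(noise, np.ones(w) / w, mode="same")
    return ForceTrace(sample_rate=cfg.force_rate, values=values + noise, t0=0.0)


# --------------------------------------------------------- rest ICMS sessions

_RESPONSE_TYPES = ("phase_locked", "non_phase_locked", "inhibited", "none")


def _draw_response_map(cfg: GeneratorConfig, sites: Sequence[int],
                       m1_channels: Sequence[int], rng: np.random.Generator) -> dict:
    base = np.array([cfg.p_phase_locked, cfg.p_non_phase_locked, cfg.p_inhibited])
    lo, hi = cfg.site_strength_range
    rmap = {}
    for s in sites:
        # each site has a coherent excitatory-vs-inhibitory character and an
        # overall strength (mirrors the site-specific spatial response
        # patterns); the character reweights excitatory vs inhibitory mass
        # while preserving the site's total responsive probability
        strength = float(rng.uniform(lo, hi))
        excitability = float(rng.choice([0.08, 0.92]))
        exc_base = base[0] + base[1]
        inh_base = base[2]
        resp = exc_base + inh_base
        if exc_base > 0 and inh_base > 0:
            w = (excitability * exc_base) / (
                excitability * exc_base + (1 - excitability) * inh_base)
            p = np.array([resp * w * base[0] / exc_base,
                          resp * w * base[1] / exc_base,
                          resp * (1 - w)])
        else:
            p = base.astype(float)
        p = np.append(p, max(1.0 - p.sum(), 0.0))
        for c in m1_channels:
            kind = _RESPONSE_TYPES[rng.choice(4, p=p / p.sum())]
            rmap[(s, c)] = {
                "type": kind,
                "gain": strength * float(rng.uniform(0.6, 1.0)) if kind != "none" else 0.0,
                "latency_ms": float(rng.uniform(3.2, 6.0)),
            }
    return rmap


def _amp_scale(cfg: GeneratorConfig, amplitude: float) -> float:
    return amplitude / max(cfg.icms_amplitudes) if amplitude > 0 else 0.0


def _freq_scale(cfg: GeneratorConfig, frequency: float) -> float:
    return cfg.freq_boost if frequency > cfg.freq_boost_above_hz else 1.0


def _apply_train_response(
    cfg: GeneratorConfig, resp: dict, base_rate: float, train: StimTrain,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Spikes of one channel inside one train window plus the rate multiplier
    applied; returns (spike times, multiplier)."""
    scale = _amp_scale(cfg, train.amplitude) * _freq_scale(cfg, train.frequency)
    mult = 1.0
    if not train.sham and resp["type"] == "non_phase_locked":
        mult = 1.0 + cfg.npl_gain * scale * resp["gain"]
    elif not train.sham and resp["type"] == "inhibited":
        mult = max(1.0 - cfg.inh_gain * scale * resp["gain"], 0.05)
    n = rng.poisson(base_rate * mult * train.duration)
    spikes = np.sort(rng.uniform(train.onset, train.onset + train.duration, n))
    if not train.sham and resp["type"] == "phase_locked":
        h = np.clip(cfg.pl_hazard * scale * resp["gain"], 0.0, 0.95)
        hit = rng.random(train.pulse_times.size) < h
        extra = (train.pulse_times[hit] + resp["latency_ms"] / 1000.0
                 + rng.uniform(0, 0.0005, int(hit.sum())))
        spikes = np.sort(np.concatenate([spikes, extra]))
    return spikes, mult


def _blank_artifacts(cfg: GeneratorConfig, spikes: np.ndarray,
                     trains: Sequence[StimTrain]) -> np.ndarray:
    """Remove spikes falling in artifact-blanked intervals of non-sham trains."""
    keep = np.ones(spikes.size, dtype=bool)
    for tr in trains:
        if tr.sham or tr.pulse_times.size == 0:
            continue
        period = 1.0 / tr.frequency
        rel = spikes - tr.onset
        inside = (rel >= 0) & (rel < tr.duration)
        phase = np.mod(rel[inside], period)
        bad = (phase < cfg.blank_post_pulse_ms / 1000.0) | (
            phase > period - cfg.blank_pre_pulse_ms / 1000.0)
        keep[np.nonzero(inside)[0][bad]] = False
    return spikes[keep]


def make_rest_icms_session(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    session_id: str = "rest-icms-0",
) -> tuple[SessionBundle, GroundTruth]:
    """Resting-state ICMS session: trains per (site, parameter set) with
    matched sham trains, and M1 multi-unit responses per ground truth.

    Parameter sets follow the experimental ladder: every amplitude level at
    the highest frequency, and every frequency level at the highest
    amplitude.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng_struct = stream(seed, session_id, "structure")
    rng_spk = stream(seed, session_id, "spikes")

    sites = [100 + i for i in range(cfg.n_stim_sites)]          # S1A channels
    m1_channels = list(range(cfg.n_m1))
    rmap = _draw_response_map(cfg, sites, m1_channels, rng_struct)

    amp_max, freq_max = max(cfg.icms_amplitudes), max(cfg.icms_frequencies)
    param_sets = [(a, freq_max) for a in cfg.icms_amplitudes]
    param_sets += [(amp_max, f) for f in cfg.icms_frequencies if (amp_max, f) not in param_sets]

    trains: list[StimTrain] = []
    t = 2.0
    cycle = cfg.icms_train_s + cfg.icms_gap_s
    for site in sites:
        for amp, freq in param_sets:
            for rep in range(cfg.icms_repetitions):
                for sham in (False, True):
                    n_p = int(round(freq * cfg.icms_train_s))
                    pulses = t + np.arange(n_p) / freq
                    trains.append(StimTrain(
                        onset=t, channel=site, amplitude=0.0 if sham else amp,
                        frequency=freq, duration=cfg.icms_train_s,
                        pulse_times=pulses, sham=sham))
                    t += cycle
    session_end = t + 2.0

    base = cfg.icms_baseline_rate * np.exp(
        rng_struct.normal(0, cfg.baseline_spread, len(m1_channels)))
    units = []
    for ci, ch in enumerate(m1_channels):
        pieces = []
        prev = 0.0
        for tr in trains:
            if tr.onset > prev:
                n = rng_spk.poisson(base[ci] * (tr.onset - prev))
                pieces.append(np.sort(rng_spk.uniform(prev, tr.onset, n)))
            resp = rmap[(tr.channel, ch)]
            spk, _ = _apply_train_response(cfg, resp, base[ci], tr, rng_spk)
            pieces.append(spk)
            prev = tr.onset + tr.duration
        n = rng_spk.poisson(base[ci] * (session_end - prev))
        pieces.append(np.sort(rng_spk.uniform(prev, session_end, n)))
        spikes = np.concatenate(pieces)
        spikes = _blank_artifacts(cfg, np.sort(spikes), trains)
        units.append(SpikeTrain(unit_id=f"M1_{ch:02d}", channel=ch, region="M1",
                                times=spikes, sorted=False))

    regions = {ch: "M1" for ch in m1_channels}
    regions.update({s: "S1A" for s in sites})
    bundle = SessionBundle(
        session_id=session_id, animal_id="synthetic-A", regions=regions,
        trials=[], units=units, force=None, stim_trains=trains,
        texture_levels=[], load_levels=[],
        meta={"generator": "rest-icms", "seed": seed,
              "param_sets": param_sets, "sites": sites},
    )
    truth = GroundTruth(
        unit_ids=[u.unit_id for u in units], baseline=base, response_map=rmap,
        net_modulation={s: _net_modulation(cfg, rmap, s, m1_channels, base) for s in sites},
    )
    return bundle, truth


def _net_modulation(cfg: GeneratorConfig, rmap: dict, site: int,
                    m1_channels: Sequence[int], base: np.ndarray) -> float:
    """Net magnitude of evoked M1 rate change (Hz, summed |per-channel
    modulation|) during a train delivered at ``site`` with the day-2
    parameters.  The grip-force deviation is proportional to this quantity,
    which couples the neural-modulation index to the behavioral one by
    construction."""
    scale = _amp_scale(cfg, cfg.day2_amplitude) * _freq_scale(cfg, cfg.day2_frequency)
    total = 0.0
    for ci, ch in enumerate(m1_channels):
        resp = rmap[(site, ch)]
        if resp["type"] == "phase_locked":
            h = min(cfg.pl_hazard * scale * resp["gain"], 0.95)
            total += h * cfg.day2_frequency
        elif resp["type"] == "non_phase_locked":
            total += base[ci] * cfg.npl_gain * scale * resp["gain"]
        elif resp["type"] == "inhibited":
            total += base[ci] * min(cfg.inh_gain * scale * resp["gain"], 0.95)
    return float(total)


# ------------------------------------------------------- day-2 grasp + ICMS

def make_grasp_icms_session(
    config: GeneratorConfig | None = None,
    pairs: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    session_id: str = "grasp-icms-0",
    tactile_levels: tuple[str, str] = ("P400", "P7000"),
    response_map: dict | None = None,
    response_seed: int | None = None,
    unit_seed: int | None = None,
) -> tuple[SessionBundle, GroundTruth]:
    """Day-2 session: blocks crossing two tactile levels x stimulation pair,
    each block ``day2_block_size`` trials evenly split between stimulated and
    control, ICMS onset at touch + ~210 ms for one second.

    ``pairs`` maps a pair label (e.g. ``"C"``, ``"D"``, ``"W"``) to an
    assignment {tactile level -> S1 site channel}.  ``response_map`` (from a
    rest-state session's ground truth, or drawn fresh when omitted) defines
    each site's effect on each M1 channel.  ``unit_seed`` pins the unit
    tuning parameters so a day-1 session (:func:`make_day1_session`) built
    with the same value records the same population.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng_struct = stream(seed, session_id, "structure")
    rng_spk = stream(seed, session_id, "spikes")
    rng_force = stream(seed, session_id, "force")

    sites = [100 + i for i in range(cfg.n_stim_sites)]
    m1_channels = list(range(cfg.n_m1))
    if response_map is None:
        rmap_rng = stream(response_seed if response_seed is not None else seed,
                          "response-map")
        response_map = _draw_response_map(cfg, sites, m1_channels, rmap_rng)
    if pairs is None:
        pairs = {"C": {tactile_levels[0]: sites[0], tactile_levels[1]: sites[1]},
                 "D": {tactile_levels[0]: sites[1], tactile_levels[1]: sites[0]}}
    for label, asg in pairs.items():
        for lvl, site in asg.items():
            if site not in sites:
                raise ValidationError(f"pair {label}: site {site} is not an S1 site")

    # --- unit tactile tuning (two texture levels, one load; multi-unit
    # channel rate scale) ---------------------------------------------------
    two_cfg = replace(cfg, texture_levels=tuple(tactile_levels),
                      load_levels=(cfg.load_levels[0],),
                      baseline_rate=cfg.icms_baseline_rate)
    rng_units = stream(unit_seed if unit_seed is not None else seed, "day-units")
    ids, channels, regions, base, tuned, a_tex, a_load, a_int = _draw_unit_params(
        two_cfg, rng_units)
    # adjacent texture levels: half the contrast of the full 3-level ladder
    tex_code = dict(zip(tactile_levels, 0.5 * _level_codes(2)))

    # --- trial/block layout ------------------------------------------------
    half = cfg.day2_block_size // 2
    blocks = [(lvl, label) for label in pairs for lvl in tactile_levels]
    trials: list[TrialRecord] = []
    stim_trains: list[StimTrain] = []
    stim_flags: list[bool] = []
    t = 5.0
    idx = 0
    n_pulses = int(round(cfg.day2_frequency * cfg.icms_train_s))
    for b, (lvl, label) in enumerate(blocks):
        flags = np.array([True] * half + [False] * (cfg.day2_block_size - half))
        rng_struct.shuffle(flags)
        site = pairs[label][lvl]
        for f in flags:
            t_cue = t
            t_touch = t_cue + cfg.reach_delay + rng_struct.uniform(-1, 1) * cfg.reach_jitter
            t_hold_end = t_touch + cfg.hold_duration
            stim_index = None
            if f:
                delay = cfg.day2_delay_median_s + rng_struct.uniform(-1, 1) * cfg.day2_delay_jitter_s
                onset = t_touch + delay
                stim_trains.append(StimTrain(
                    onset=onset, channel=site, amplitude=cfg.day2_amplitude,
                    frequency=cfg.day2_frequency, duration=cfg.icms_train_s,
                    pulse_times=onset + np.arange(n_pulses) / cfg.day2_frequency,
                    sham=False))
                stim_index = len(stim_trains) - 1
            trials.append(TrialRecord(index=idx, block=b, texture=lvl,
                                      load=cfg.load_levels[0], t_cue=t_cue,
                                      t_touch=t_touch, t_hold_end=t_hold_end,
                                      stim_index=stim_index, is_control=not f))
            stim_flags.append(bool(f))
            idx += 1
            t += cfg.trial_period
    session_end = t + 2.0

    # --- spikes ------------------------------------------------------------
    n_bins = int(round((TRIAL_WIN[1] - TRIAL_WIN[0]) / BIN_S))
    t_ms = (TRIAL_WIN[0] + np.arange(n_bins) * BIN_S) * 1000.0
    touch = np.array([tr.t_touch for tr in trials])
    x_tex = np.array([tex_code[tr.texture] for tr in trials])

    scale = _amp_scale(cfg, cfg.day2_amplitude) * _freq_scale(cfg, cfg.day2_frequency)
    units = []
    for i, u in enumerate(ids):
        lograte = np.empty((len(trials), n_bins))
        for k in range(len(trials)):
            lograte[k] = _tuning_lograte(cfg, t_ms, base[i], a_tex[i], a_load[i],
                                         a_int[i], x_tex[k], 0.0)
        # sustained ICMS modulation enters the log rate during the train
        if regions[i] == "M1":
            for k, tr in enumerate(trials):
                if tr.stim_index is None:
                    continue
                train = stim_trains[tr.stim_index]
                resp = response_map[(train.channel, channels[i])]
                rel0 = int(round((train.onset - tr.t_touch - TRIAL_WIN[0]) / BIN_S))
                rel1 = min(rel0 + int(round(train.duration / BIN_S)), n_bins)
                if resp["type"] == "non_phase_locked":
                    lograte[k, rel0:rel1] += np.log1p(cfg.npl_gain * scale * resp["gain"])
                elif resp["type"] == "inhibited":
                    lograte[k, rel0:rel1] += np.log(
                        max(1.0 - cfg.inh_gain * scale * resp["gain"], 0.05))
        binary = _sample_binary(lograte, rng_spk)
        rows, cols = np.nonzero(binary)
        times = touch[rows] + TRIAL_WIN[0] + (cols + 0.5) * BIN_S
        # phase-locked extra spikes, superposed per pulse
        if regions[i] == "M1":
            extras = []
            for tr in trials:
                if tr.stim_index is None:
                    continue
                train = stim_trains[tr.stim_index]
                resp = response_map[(train.channel, channels[i])]
                if resp["type"] != "phase_locked":
                    continue
                h = np.clip(cfg.pl_hazard * scale * resp["gain"], 0.0, 0.95)
                hit = rng_spk.random(train.pulse_times.size) < h
                extras.append(train.pulse_times[hit] + resp["latency_ms"] / 1000.0
                              + rng_spk.uniform(0, 0.0005, int(hit.sum())))
            if extras:
                times = np.concatenate([times] + extras)
        gap_sp = _gap_spikes(base[i], _session_gaps(touch, session_end), rng_spk)
        times = np.sort(np.concatenate([times, gap_sp]))
        times = _blank_artifacts(cfg, times, stim_trains)
        units.append(SpikeTrain(unit_id=u, channel=channels[i], region=regions[i],
                                times=times, sorted=False))

    # --- force with ICMS-coupled deviation ---------------------------------
    net = {s: _net_modulation(cfg, response_map, s, m1_channels, base[:cfg.n_m1])
           for s in sites}
    deviation = {}
    for tr in trials:
        if tr.stim_index is not None:
            train = stim_trains[tr.stim_index]
            deviation[tr.index] = (train.onset,
                                   cfg.force_neural_coupling * net[train.channel])
    force = _make_force(two_cfg, trials, session_end, x_tex, rng_force,
                        deviation=deviation)

    region_map = dict(zip(channels, regions))
    region_map.update({s: "S1A" for s in sites})
    bundle = SessionBundle(
        session_id=session_id, animal_id="synthetic-A", regions=region_map,
        trials=trials, units=units, force=force, stim_trains=stim_trains,
        texture_levels=list(tactile_levels), load_levels=[cfg.load_levels[0]],
        meta={"generator": "grasp-icms", "seed": seed,
              "pairs": {k: {str(l): s for l, s in v.items()} for k, v in pairs.items()},
              "blocks": [{"block": b, "level": lvl, "pair": label}
                         for b, (lvl, label) in enumerate(blocks)],
              "delay_median_s": cfg.day2_delay_median_s},
    )
    truth = GroundTruth(
        unit_ids=ids, tuned=tuned, alpha_texture=a_tex, alpha_load=a_load,
        alpha_interaction=a_int, baseline=base, response_map=response_map,
        net_modulation=net,
        force_effect={k: cfg.force_neural_coupling * v for k, v in net.items()},
        condition_codes={"texture": tex_code},
    )
    return bundle, truth


def make_day1_session(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    session_id: str = "day1-0",
    tactile_levels: tuple[str, str] = ("P400", "P7000"),
    trials_per_level: int = 50,
    unit_seed: int | None = None,
) -> tuple[SessionBundle, GroundTruth]:
    """Day-1 grasping session under two tactile levels, no stimulation.

    Four blocks with the second half mirroring the first (T1/T2/T2/T1).
    Built from the same unit-parameter stream as
    :func:`make_grasp_icms_session` given the same ``unit_seed``, so the
    day-2 session records the identical population — the premise of
    training decoders on day 1 and testing on day 2.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    # day-1/day-2 M1 and S1 signals are threshold-crossing channels; their
    # rates sit on the multi-unit scale
    two_cfg = replace(cfg, texture_levels=tuple(tactile_levels),
                      load_levels=(cfg.load_levels[0],),
                      baseline_rate=cfg.icms_baseline_rate)
    rng_units = stream(unit_seed if unit_seed is not None else seed, "day-units")
    ids, channels, regions, base, tuned, a_tex, a_load, a_int = _draw_unit_params(
        two_cfg, rng_units)
    rng_struct = stream(seed, session_id, "structure")
    rng_spk = stream(seed, session_id, "spikes")
    rng_force = stream(seed, session_id, "force")

    half = trials_per_level // 2
    blocks = [tactile_levels[0], tactile_levels[1],
              tactile_levels[1], tactile_levels[0]]
    counts = [half, half, trials_per_level - half, trials_per_level - half]
    trials: list[TrialRecord] = []
    t, idx = 5.0, 0
    for b, (lvl, n_b) in enumerate(zip(blocks, counts)):
        for _ in range(n_b):
            t_cue = t
            t_touch = t_cue + cfg.reach_delay + rng_struct.uniform(-1, 1) * cfg.reach_jitter
            trials.append(TrialRecord(index=idx, block=b, texture=lvl,
                                      load=cfg.load_levels[0], t_cue=t_cue,
                                      t_touch=t_touch,
                                      t_hold_end=t_touch + cfg.hold_duration))
            idx += 1
            t += cfg.trial_period
    session_end = t + 2.0

    # adjacent texture levels: half the contrast of the full 3-level ladder
    tex_code = dict(zip(tactile_levels, 0.5 * _level_codes(2)))
    x_tex = np.array([tex_code[tr.texture] for tr in trials])
    touch = np.array([tr.t_touch for tr in trials])
    n_bins = int(round((TRIAL_WIN[1] - TRIAL_WIN[0]) / BIN_S))
    t_ms = (TRIAL_WIN[0] + np.arange(n_bins) * BIN_S) * 1000.0

    units = []
    for i, u in enumerate(ids):
        lograte = np.empty((len(trials), n_bins))
        for k in range(len(trials)):
            lograte[k] = _tuning_lograte(cfg, t_ms, base[i], a_tex[i], a_load[i],
                                         a_int[i], x_tex[k], 0.0)
        binary = _sample_binary(lograte, rng_spk)
        rows, cols = np.nonzero(binary)
        in_trial = touch[rows] + TRIAL_WIN[0] + (cols + 0.5) * BIN_S
        gap_sp = _gap_spikes(base[i], _session_gaps(touch, session_end), rng_spk)
        units.append(SpikeTrain(unit_id=u, channel=channels[i], region=regions[i],
                                times=np.sort(np.concatenate([in_trial, gap_sp])),
                                sorted=False))

    force = _make_force(two_cfg, trials, session_end, x_tex, rng_force)
    region_map = dict(zip(channels, regions))
    region_map.update({100 + i: "S1A" for i in range(cfg.n_stim_sites)})
    bundle = SessionBundle(
        session_id=session_id, animal_id="synthetic-A", regions=region_map,
        trials=trials, units=units, force=force,
        texture_levels=list(tactile_levels), load_levels=[cfg.load_levels[0]],
        meta={"generator": "day1", "seed": seed,
              "delay_median_s": cfg.day2_delay_median_s},
    )
    truth = GroundTruth(unit_ids=ids, tuned=tuned, alpha_texture=a_tex,
                        alpha_load=a_load, alpha_interaction=a_int,
                        baseline=base, condition_codes={"texture": tex_code})
    return bundle, truth


def _session_gaps(touch: np.ndarray, session_end: float) -> list[tuple[float, float]]:
    spans = [(t0 + TRIAL_WIN[0], t0 + TRIAL_WIN[1]) for t0 in touch]
    gaps, prev = [], 0.0
    for a, b in spans:
        gaps.append((prev, a))
        prev = b
    gaps.append((prev, session_end))
    return gaps
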