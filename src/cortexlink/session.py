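"""Session data model, plain-text bundle I/O, and alignment/windowing primitives.

A *session bundle* holds everything one recording session produced: a trial
table (texture x load conditions with behavioral event times), spike trains
per unit or multi-unit channel from M1 and the two S1 arrays, a continuous
grip-force trace, and any intracortical microstimulation (ICMS) trains that
were delivered.  All downstream stages (tuning, decoding, connectivity, ICMS
response mapping, modulation indices) consume this one container.

Conventions
-----------
* Time is kept in seconds on the session clock internally; analysis-facing
  interfaces (window grids, alignment spans) speak milliseconds relative to a
  behavioral event.
* Windows are half-open ``[start, start + width)`` so a spike on a boundary
  belongs to exactly one window.
* On disk a bundle is a directory of plain-text tables (``trials.csv``,
  ``spikes.csv``, ``force.csv``, ``stim.csv``) plus a ``manifest.json`` —
  portable and diff-able, no binary container required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TrialRecord",
    "SpikeTrain",
    "ForceTrace",
    "StimTrain",
    "WindowGrid",
    "SessionBundle",
    "write_bundle",
    "read_bundle",
    "align_spikes",
    "window_counts",
]

REGIONS = ("M1", "S1A", "S1B")


class ValidationError(ValueError):
    """A bundle component violates a structural invariant; names the field."""


@dataclass
class TrialRecord:
    index: int
    block: int
    texture: str
    load: float            # grams
    t_cue: float           # seconds, session clock
    t_touch: float
    t_hold_end: float
    stim_index: int | None = None   # index into SessionBundle.stim_trains
    is_control: bool = False

    def validate(self) -> None:
        if not (self.t_cue < self.t_touch < self.t_hold_end):
            raise ValidationError(
                f"trial {self.index}: event times must increase "
                f"(t_cue={self.t_cue}, t_touch={self.t_touch}, "
                f"t_hold_end={self.t_hold_end})"
            )


@dataclass
class SpikeTrain:
    unit_id: str
    channel: int
    region: str
    times: np.ndarray       # seconds, nondecreasing
    sorted: bool = True     # sorted unit vs threshold-crossing multi-unit

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unit {self.unit_id}: unknown region {self.region!r}")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not nondecreasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else 0.0


@dataclass
class ForceTrace:
    sample_rate: float      # Hz
    values: np.ndarray
    t0: float = 0.0         # session time of first sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError(f"force: sample_rate must be > 0, got {self.sample_rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("force: values contain non-finite entries")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def slice(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples with time in ``[t_start, t_stop)``."""
        i0 = int(np.ceil((t_start - self.t0) * self.sample_rate - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.sample_rate - 1e-9))
        i0, i1 = max(i0, 0), max(min(i1, self.values.size), 0)
        return self.values[i0:i1]


@dataclass
class StimTrain:
    onset: float            # seconds
    channel: int            # stimulated S1 site
    amplitude: float        # microamperes; 0 for sham
    frequency: float        # Hz
    duration: float         # seconds
    pulse_times: np.ndarray  # seconds, within [onset, onset + duration]
    sham: bool = False

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)

    def validate(self) -> None:
        if self.pulse_times.size:
            lo, hi = self.pulse_times.min(), self.pulse_times.max()
            if lo < self.onset - 1e-9 or hi > self.onset + self.duration + 1e-9:
                raise ValidationError("stim train: pulse_times outside [onset, onset+duration]")
        if self.sham and self.amplitude != 0:
            raise ValidationError("stim train: sham trains must have amplitude 0")


@dataclass
class WindowGrid:
    """Sliding analysis windows, in ms relative to an alignment event."""

    width: float                    # ms
    step: float                     # ms
    starts: np.ndarray              # ms, strictly increasing

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        if self.starts.size and np.any(np.diff(self.starts) <= 0):
            raise ValidationError("window grid: starts must be strictly increasing")
        if self.width <= 0:
            raise ValidationError("window grid: width must be > 0")

    @classmethod
    def regular(cls, first_start: float, last_start: float, width: float, step: float) -> "WindowGrid":
        n = int(round((last_start - first_start) / step)) + 1
        return cls(width=width, step=step, starts=first_start + step * np.arange(n))

    @classmethod
    def tuning_default(cls) -> "WindowGrid":
        # 23 starts from -200 to +900 ms: 200 ms window, 50 ms step.
        return cls.regular(-200.0, 900.0, 200.0, 50.0)

    @classmethod
    def cgc_default(cls) -> "WindowGrid":
        # 300 ms window, 50 ms step spanning -500..1000 ms.
        return cls.regular(-500.0, 700.0, 300.0, 50.0)

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2.0

    @property
    def span(self) -> tuple[float, float]:
        return float(self.starts[0]), float(self.starts[-1] + self.width)


@dataclass
class SessionBundle:
    session_id: str
    animal_id: str
    regions: dict[int, str]            # channel -> region label
    trials: list[TrialRecord]
    units: list[SpikeTrain]
    force: ForceTrace | None = None
    stim_trains: list[StimTrain] = field(default_factory=list)
    texture_levels: list[str] = field(default_factory=list)   # ordered by roughness
    load_levels: list[float] = field(default_factory=list)    # grams
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ helpers
    @property
    def duration(self) -> float:
        ends = [t.t_hold_end for t in self.trials]
        ends += [tr.onset + tr.duration for tr in self.stim_trains]
        if self.force is not None and self.force.values.size:
            ends.append(self.force.times[-1])
        for u in self.units:
            if u.times.size:
                ends.append(float(u.times[-1]))
        return max(ends, default=0.0) + 1.0

    def units_in(self, region: str) -> list[SpikeTrain]:
        return [u for u in self.units if u.region == region]

    def trial_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "block": [t.block for t in self.trials],
                "texture": [t.texture for t in self.trials],
                "load": [t.load for t in self.trials],
                "t_cue": [t.t_cue for t in self.trials],
                "t_touch": [t.t_touch for t in self.trials],
                "t_hold_end": [t.t_hold_end for t in self.trials],
                "stim_index": [t.stim_index for t in self.trials],
                "is_control": [t.is_control for t in self.trials],
            }
        )

    def validate(self) -> None:
        duration = self.duration
        for trial in self.trials:
            trial.validate()
            if self.texture_levels and trial.texture not in self.texture_levels:
                raise ValidationError(
                    f"trial {trial.index}: texture {trial.texture!r} not in declared levels"
                )
            if self.load_levels and trial.load not in self.load_levels:
                raise ValidationError(
                    f"trial {trial.index}: load {trial.load} not in declared levels"
                )
            if trial.stim_index is not None and not (
                0 <= trial.stim_index < len(self.stim_trains)
            ):
                raise ValidationError(f"trial {trial.index}: stim_index out of range")
        for unit in self.units:
            unit.validate()
            if unit.times.size and (unit.times[0] < 0 or unit.times[-1] > duration):
                raise ValidationError(
                    f"unit {unit.unit_id}: spike times outside session [0, {duration:.3f}] s"
                )
            if unit.channel in self.regions and self.regions[unit.channel] != unit.region:
                raise ValidationError(
                    f"unit {unit.unit_id}: region {unit.region} inconsistent with channel map"
                )
        if self.force is not None:
            self.force.validate()
        for i, train in enumerate(self.stim_trains):
            train.validate()
            if train.channel not in self.regions:
                raise ValidationError(f"stim train {i}: channel {train.channel} not in channel map")


# ---------------------------------------------------------------------- bundle IO

_MANIFEST = "manifest.json"


def write_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a validated bundle as a directory of plain-text tables.

    Returns the manifest path.  Raises :class:`ValidationError` before any
    file is written if an invariant fails.
    """
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    bundle.trial_table().to_csv(path / "trials.csv", index=False)

    spikes = pd.DataFrame(
        {
            "unit_id": np.repeat([u.unit_id for u in bundle.units],
                                 [u.n_spikes for u in bundle.units]),
            "time_s": np.concatenate([u.times for u in bundle.units])
            if bundle.units else np.array([]),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False)

    if bundle.force is not None:
        pd.DataFrame(
            {"time_s": bundle.force.times, "value": bundle.force.values}
        ).to_csv(path / "force.csv", index=False)

    stim_rows = []
    for i, tr in enumerate(bundle.stim_trains):
        for j, pt in enumerate(tr.pulse_times):
            stim_rows.append((i, tr.onset, tr.channel, tr.amplitude, tr.frequency,
                              tr.duration, int(tr.sham), j, pt))
    pd.DataFrame(
        stim_rows,
        columns=["train", "onset", "channel", "amplitude", "frequency",
                 "duration", "sham", "pulse", "time_s"],
    ).to_csv(path / "stim.csv", index=False)

    n_cells = int(bundle.trial_table().groupby(["texture", "load"]).ngroups) if bundle.trials else 0
    manifest = {
        "format": "cortexlink-bundle",
        "version": 1,
        "session_id": bundle.session_id,
        "animal_id": bundle.animal_id,
        "regions": {str(k): v for k, v in bundle.regions.items()},
        "texture_levels": bundle.texture_levels,
        "load_levels": bundle.load_levels,
        "units": [
            {"unit_id": u.unit_id, "channel": u.channel, "region": u.region,
             "sorted": u.sorted}
            for u in bundle.units
        ],
        "force": None if bundle.force is None else {
            "sample_rate": bundle.force.sample_rate, "t0": bundle.force.t0,
        },
        "n_trials": len(bundle.trials),
        "n_condition_cells": n_cells,
        "tables": ["trials.csv", "spikes.csv", "stim.csv"]
        + (["force.csv"] if bundle.force is not None else []),
        "meta": bundle.meta,
    }
    manifest_path = path / _MANIFEST
    manifest_path.write_text(json.dumps(manifest, indent=1, default=_json_default))
    return manifest_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_bundle(path: str | Path) -> SessionBundle:
    """Read a bundle directory written by :func:`write_bundle` and validate it."""
    path = Path(path)
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {_MANIFEST} in {path}")
    manifest = json.loads(manifest_path.read_text())

    for table in manifest.get("tables", []):
        if not (path / table).exists():
            raise FileNotFoundError(f"manifest references missing table {table} in {path}")

    trials_df = pd.read_csv(path / "trials.csv")
    trials = [
        TrialRecord(
            index=int(r["index"]), block=int(r["block"]), texture=str(r["texture"]),
            load=float(r["load"]), t_cue=float(r["t_cue"]), t_touch=float(r["t_touch"]),
            t_hold_end=float(r["t_hold_end"]),
            stim_index=None if pd.isna(r["stim_index"]) else int(r["stim_index"]),
            is_control=bool(r["is_control"]),
        )
        for _, r in trials_df.iterrows()
    ]

    spikes_df = pd.read_csv(path / "spikes.csv")
    by_unit = (
        {k: g["time_s"].to_numpy() for k, g in spikes_df.groupby("unit_id", sort=False)}
        if len(spikes_df) else {}
    )
    units = [
        SpikeTrain(
            unit_id=u["unit_id"], channel=int(u["channel"]), region=u["region"],
            times=np.sort(by_unit.get(u["unit_id"], np.array([]))),
            sorted=bool(u["sorted"]),
        )
        for u in manifest["units"]
    ]

    force = None
    if manifest.get("force") is not None:
        force_df = pd.read_csv(path / "force.csv")
        force = ForceTrace(
            sample_rate=float(manifest["force"]["sample_rate"]),
            values=force_df["value"].to_numpy(),
            t0=float(manifest["force"]["t0"]),
        )

    stim_trains: list[StimTrain] = []
    stim_df = pd.read_csv(path / "stim.csv")
    if len(stim_df):
        for _, g in stim_df.groupby("train", sort=True):
            first = g.iloc[0]
            stim_trains.append(
                StimTrain(
                    onset=float(first["onset"]), channel=int(first["channel"]),
                    amplitude=float(first["amplitude"]), frequency=float(first["frequency"]),
                    duration=float(first["duration"]),
                    pulse_times=np.sort(g["time_s"].to_numpy()),
                    sham=bool(first["sham"]),
                )
            )

    bundle = SessionBundle(
        session_id=manifest["session_id"],
        animal_id=manifest["animal_id"],
        regions={int(k): v for k, v in manifest["regions"].items()},
        trials=trials,
        units=units,
        force=force,
        stim_trains=stim_trains,
        texture_levels=list(manifest.get("texture_levels", [])),
        load_levels=[float(x) for x in manifest.get("load_levels", [])],
        meta=manifest.get("meta", {}),
    )
    bundle.validate()
    return bundle


# ------------------------------------------------------------ alignment/windowing

_EVENTS = {"cue": "t_cue", "touch": "t_touch", "hold_end": "t_hold_end"}


def event_times(trials: Sequence[TrialRecord], event: str) -> np.ndarray:
    """Session-clock times of a named behavioral event, one per trial.

    ``stim_onset`` resolves through each trial's stimulation train; trials
    without one (controls) fall back to touch + the session's nominal delay
    recorded in their bundle — callers that need that fallback should pass
    explicit times instead.
    """
    if event in _EVENTS:
        return np.array([getattr(t, _EVENTS[event]) for t in trials], dtype=float)
    raise KeyError(f"unknown event label {event!r}; expected one of {sorted(_EVENTS)}")


def align_spikes(
    train: SpikeTrain,
    trials: Sequence[TrialRecord],
    event: str = "touch",
    span: tuple[float, float] = (-500.0, 1500.0),
    times: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-trial spike times in ms relative to a behavioral event.

    ``span`` is half-open ``[lo, hi)`` in ms.  ``times`` overrides the event
    lookup with explicit per-trial alignment times (seconds) — used e.g. to
    align on stimulation onset.
    """
    t_event = np.asarray(times, dtype=float) if times is not None else event_times(trials, event)
    lo, hi = span
    out: list[np.ndarray] = []
    spikes = train.times
    for t0 in t_event:
        a = np.searchsorted(spikes, t0 + lo / 1000.0, side="left")
        b = np.searchsorted(spikes, t0 + hi / 1000.0, side="left")
        rel = (spikes[a:b] - t0) * 1000.0
        out.append(rel[(rel >= lo) & (rel < hi)])
    return out


def window_counts(raster: Sequence[np.ndarray], grid: WindowGrid) -> np.ndarray:
    """Trials x windows firing-rate matrix (Hz) from an aligned raster.

    Each entry is the spike count in the half-open window ``[start,
    start+width)`` divided by the window width.
    """
    starts = grid.starts
    width = grid.width
    rates = np.zeros((len(raster), starts.size))
    for i, rel in enumerate(raster):
        if rel.size == 0:
            continue
        # half-open windows: count spikes with start <= t < start + width
        lo = np.searchsorted(rel, starts, side="left")
        hi = np.searchsorted(rel, starts + width, side="left")
        rates[i] = hi - lo
    return rates / (width / 1000.0)


def binned_counts(
    raster: Sequence[np.ndarray], t_start: float, t_stop: float, bin_ms: float = 1.0
) -> np.ndarray:
    """Trials x bins spike-count matrix on a contiguous 1 ms (default) grid.

    Used by the spectral pipeline, which needs raw counts rather than rates.
    """
    edges = np.arange(t_start, t_stop + bin_ms / 2, bin_ms)
    out = np.zeros((len(raster), edges.size - 1), dtype=float)
    for i, rel in enumerate(raster):
        if rel.size:
            out[i], _ = np.histogram(rel, bins=edges)
    return out
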