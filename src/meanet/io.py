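"""Data model and file I/O for MEA recordings, spike events and electrode layouts.

Conventions
-----------
* Times are seconds (float) everywhere; sample indices are internal only.
  All windows and bins are half-open, ``[t0, t1)``.
* Voltages are microvolts; electrode coordinates are micrometres with the
  origin at the bottom-left of the chip.
* A raw recording on disk is a little-endian float32 matrix (channel-major)
  in ``<name>.f32`` with a JSON sidecar ``<name>.json`` holding
  ``{fs_hz, unit, channel_ids, layout_file | layout}``.
* Spike events are TSV with header ``electrode_id\ttime_s\tamplitude_uV``.
* Layouts are TSV with header ``electrode_id\tx_um\ty_um``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

__all__ = [
    "ElectrodeLayout",
    "Recording",
    "SpikeTrainSet",
    "read_layout",
    "write_layout",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "electrode_distance",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode ids and their positions on the chip, in µm."""

    ids: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 2) float, µm

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=int)
        pos = np.asarray(self.positions, dtype=float)
        if ids.ndim != 1 or pos.shape != (ids.size, 2):
            raise ValidationError("layout requires ids (n,) and positions (n, 2)")
        if ids.size < 1:
            raise ValidationError("layout must contain at least one electrode")
        if np.unique(ids).size != ids.size:
            raise ValidationError("electrode ids must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("electrode positions must be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, pitch_um: float, first_id: int = 1) -> "ElectrodeLayout":
        """Regular grid, ids row-major starting at ``first_id``, row 0 at y=0."""
        ids = np.arange(first_id, first_id + n_rows * n_cols)
        xs, ys = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        pos = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * pitch_um
        return cls(ids, pos)

    def __len__(self) -> int:
        return int(self.ids.size)

    def index_of(self, electrode_id: int) -> int:
        hits = np.flatnonzero(self.ids == electrode_id)
        if hits.size == 0:
            raise KeyError(f"unknown electrode id {electrode_id}")
        return int(hits[0])

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]


def electrode_distance(layout: ElectrodeLayout, id_a: int, id_b: int) -> float:
    """Euclidean distance in µm between two electrodes of the layout."""
    pa = layout.position_of(id_a)
    pb = layout.position_of(id_b)
    return float(np.hypot(*(pa - pb)))


@dataclass
class Recording:
    """Multi-channel extracellular voltage traces.

    ``traces`` is (n_channels, n_samples) in µV, ``fs`` the per-channel
    sampling rate in Hz (20 kHz for the systems this package models),
    ``t0`` the start time in seconds. ``meta`` carries processing tags,
    e.g. ``hp_cutoff_hz`` once a high-pass filter has been applied.
    """

    traces: np.ndarray
    fs: float
    layout: ElectrodeLayout
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.traces.shape[0] != len(self.layout):
            raise ConsistencyError(
                f"{self.traces.shape[0]} trace channels but layout has {len(self.layout)} electrodes"
            )

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, electrode_id: int) -> np.ndarray:
        return self.traces[self.layout.index_of(electrode_id)]


class SpikeTrainSet:
    """Per-electrode sorted spike times (s) with signed peak amplitudes (µV)."""

    def __init__(self, trains: dict, duration: float):
        if duration < 0:
            raise ValidationError("duration must be >= 0")
        self.duration = float(duration)
        self.trains = {}
        for eid, (times, amps) in trains.items():
            times = np.asarray(times, dtype=float)
            amps = np.asarray(amps, dtype=float)
            if times.shape != amps.shape:
                raise ValidationError(f"electrode {eid}: times/amplitudes length mismatch")
            if times.size and (times.min() < 0 or times.max() > max(duration, 0.0)):
                raise ValidationError(f"electrode {eid}: spike times outside [0, duration]")
            if not np.all(np.isfinite(amps)):
                raise ValidationError(f"electrode {eid}: non-finite amplitudes")
            order = np.argsort(times, kind="stable")
            self.trains[int(eid)] = (times[order], amps[order])

    @property
    def electrode_ids(self):
        return sorted(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t, _ in self.trains.values())

    def times(self, electrode_id: int) -> np.ndarray:
        return self.trains[electrode_id][0]

    def pooled_times(self) -> np.ndarray:
        """All spike times pooled across electrodes, sorted."""
        if not self.trains:
            return np.empty(0)
        allt = np.concatenate([t for t, _ in self.trains.values()]) if self.trains else np.empty(0)
        return np.sort(allt, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eid in self.electrode_ids:
            t, a = self.trains[eid]
            rows.append(pd.DataFrame({"electrode_id": eid, "time_s": t, "amplitude_uV": a}))
        if not rows:
            return pd.DataFrame(columns=["electrode_id", "time_s", "amplitude_uV"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, duration: float | None = None,
                   layout: ElectrodeLayout | None = None) -> "SpikeTrainSet":
        required = {"electrode_id", "time_s", "amplitude_uV"}
        if not required.issubset(df.columns):
            raise FormatError(f"event table must have columns {sorted(required)}")
        if len(df) and df["time_s"].min() < 0:
            raise ValidationError("negative spike time in event table")
        if layout is not None:
            unknown = set(df["electrode_id"].astype(int)) - set(layout.ids.tolist())
            if unknown:
                raise ValidationError(f"event table references unknown electrodes {sorted(unknown)}")
        if duration is None:
            duration = float(df["time_s"].max()) if len(df) else 0.0
        trains = {
            int(eid): (g["time_s"].to_numpy(), g["amplitude_uV"].to_numpy())
            for eid, g in df.groupby("electrode_id", sort=True)
        }
        return cls(trains, duration)


# ---------------------------------------------------------------------------
# file I/O


def write_layout(layout: ElectrodeLayout, path: str) -> None:
    df = pd.DataFrame({"electrode_id": layout.ids,
                       "x_um": layout.positions[:, 0],
                       "y_um": layout.positions[:, 1]})
    df.to_csv(path, sep="\t", index=False)


def read_layout(path: str) -> ElectrodeLayout:
    df = pd.read_csv(path, sep="\t")
    required = {"electrode_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise FormatError(f"layout file must have columns {sorted(required)}")
    return ElectrodeLayout(df["electrode_id"].to_numpy(int),
                           df[["x_um", "y_um"]].to_numpy(float))


def _base(path: str) -> str:
    for ext in (".f32", ".json"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def write_recording(rec: Recording, path: str) -> None:
    """Write ``<base>.f32`` + ``<base>.json`` (+ ``<base>.layout.tsv``)."""
    base = _base(path)
    rec.traces.astype("<f4").tofile(base + ".f32")
    layout_file = os.path.basename(base) + ".layout.tsv"
    write_layout(rec.layout, os.path.join(os.path.dirname(base) or ".", layout_file))
    sidecar = {
        "fs_hz": rec.fs,
        "unit": "uV",
        "t0_s": rec.t0,
        "channel_ids": [int(i) for i in rec.layout.ids],
        "layout_file": layout_file,
        "meta": rec.meta,
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_recording(path: str) -> Recording:
    base = _base(path)
    sidecar_path = base + ".json"
    if not os.path.exists(sidecar_path):
        raise FormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        side = json.load(fh)
    for key in ("fs_hz", "channel_ids"):
        if key not in side:
            raise FormatError(f"sidecar missing required key '{key}'")
    fs = float(side["fs_hz"])
    if fs <= 0:
        raise ValidationError(f"sidecar fs_hz must be positive, got {fs}")
    channel_ids = [int(i) for i in side["channel_ids"]]
    if "layout_file" in side:
        layout = read_layout(os.path.join(os.path.dirname(base) or ".", side["layout_file"]))
    elif "layout" in side:
        arr = np.asarray(side["layout"], dtype=float)
        layout = ElectrodeLayout(arr[:, 0].astype(int), arr[:, 1:3])
    else:
        raise FormatError("sidecar must carry 'layout_file' or inline 'layout'")
    if list(layout.ids) != channel_ids:
        raise ConsistencyError("sidecar channel_ids do not match layout electrode ids")
    raw = np.fromfile(base + ".f32", dtype="<f4")
    n_ch = len(channel_ids)
    if raw.size % n_ch != 0:
        raise ConsistencyError(
            f"trace file has {raw.size} samples, not divisible by {n_ch} channels")
    traces = raw.reshape(n_ch, raw.size // n_ch)
    return Recording(traces, fs, layout, t0=float(side.get("t0_s", 0.0)),
                     meta=dict(side.get("meta", {})))


def write_events(spikes: SpikeTrainSet, path: str) -> None:
    # default float repr is shortest-round-trip, so read_events(write_events(x)) is exact
    spikes.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path: str, duration: float | None = None,
                layout: ElectrodeLayout | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path, sep="\t")
    return SpikeTrainSet.from_frame(df, duration=duration, layout=layout)
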