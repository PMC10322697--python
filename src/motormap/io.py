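"""Session container I/O.

A session on disk is a directory holding

* ``data.h5``      — HDF5 file with dataset ``data`` (channels x samples,
  float32, microvolts) and a scalar attribute ``fs`` (Hz),
* ``events.tsv``   — task epochs with columns ``onset``, ``duration``
  (seconds), ``trial_type`` (hand/tongue/foot/rest), ``source`` (cue/emg)
  and ``following`` (for rest epochs, the movement type they follow),
* ``channels.tsv`` — one row per channel: ``name``, ``kind`` (seeg/emg),
  ``lead_id``, ``segment_id``, ``contact_index``, ``x``, ``y``, ``z``.

Numeric payloads round-trip bit-exactly. No science lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

MOVEMENTS = ("hand", "tongue", "foot")
TRIAL_TYPES = MOVEMENTS + ("rest",)

CHANNEL_COLUMNS = ["name", "kind", "lead_id", "segment_id", "contact_index", "x", "y", "z"]
EVENT_COLUMNS = ["onset", "duration", "trial_type", "source", "following"]


class SessionFormatError(ValueError):
    """Raised when an on-disk session or in-memory container violates the format."""


@dataclass
class Recording:
    """Multichannel voltage timeseries with per-channel metadata.

    ``data`` is channels x samples in microvolts; ``channel_table`` has one
    row per data row (see :mod:`motormap.io` for columns). Coordinates may
    be NaN when unknown.
    """

    data: np.ndarray
    fs: float
    channel_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise SessionFormatError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise SessionFormatError(f"fs must be positive, got {self.fs}")
        self.channel_table = self.channel_table.reset_index(drop=True)
        missing = set(CHANNEL_COLUMNS[:5]) - set(self.channel_table.columns)
        if missing:
            raise SessionFormatError(f"channel table missing columns: {sorted(missing)}")
        for c in ("x", "y", "z"):
            if c not in self.channel_table.columns:
                self.channel_table[c] = np.nan
        if len(self.channel_table) != self.data.shape[0]:
            raise SessionFormatError(
                f"channel table has {len(self.channel_table)} rows for "
                f"{self.data.shape[0]} data rows"
            )
        bad_kind = set(self.channel_table["kind"]) - {"seeg", "emg"}
        if bad_kind:
            raise SessionFormatError(f"unknown channel kind(s): {sorted(bad_kind)}")
        seeg = self.channel_table[self.channel_table["kind"] == "seeg"]
        for (lead, seg), grp in seeg.groupby(["lead_id", "segment_id"], sort=False):
            idx = grp["contact_index"].to_numpy()
            if not np.all(np.diff(idx) > 0):
                raise SessionFormatError(
                    f"contact_index not strictly increasing on lead {lead!r} "
                    f"segment {seg!r}"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels_of_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero((self.channel_table["kind"] == kind).to_numpy())


@dataclass
class TaskEvents:
    """Task epochs: movement cues and the rest periods between them.

    Rest rows carry in ``following`` the movement type of the epoch they
    follow; movement-vs-rest statistics pair each movement with the rest
    that followed it to dodge the post-movement beta rebound.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        missing = set(EVENT_COLUMNS[:4]) - set(t.columns)
        if missing:
            raise SessionFormatError(f"events table missing columns: {sorted(missing)}")
        if "following" not in t.columns:
            t["following"] = "n/a"
        t["following"] = t["following"].fillna("n/a")
        if len(t):
            bad = set(t["trial_type"]) - set(TRIAL_TYPES)
            if bad:
                raise SessionFormatError(f"unknown trial_type(s): {sorted(bad)}")
            if (t["duration"].to_numpy() <= 0).any():
                raise SessionFormatError("event durations must be positive")
            for source, grp in t.groupby("source", sort=False):
                onset = grp["onset"].to_numpy(float)
                if not np.all(np.diff(onset) >= 0):
                    raise SessionFormatError(f"onsets not non-decreasing for source {source!r}")
                end = onset + grp["duration"].to_numpy(float)
                if np.any(onset[1:] < end[:-1] - 1e-9):
                    raise SessionFormatError(f"overlapping epochs from source {source!r}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def of_type(self, trial_type: str) -> pd.DataFrame:
        return self.table[self.table["trial_type"] == trial_type]

    def movement_epochs(self) -> pd.DataFrame:
        return self.table[self.table["trial_type"] != "rest"]

    def rest_following(self, movement: str) -> pd.DataFrame:
        t = self.table
        return t[(t["trial_type"] == "rest") & (t["following"] == movement)]


def write_session(recording: Recording, events: TaskEvents, path: str | Path) -> Path:
    """Write a session directory; refuses non-finite voltage data."""
    if not np.isfinite(recording.data).all():
        raise SessionFormatError("recording data contains NaN/inf; refusing to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "data.h5", "w") as f:
        d = f.create_dataset("data", data=recording.data.astype(np.float32, copy=False))
        d.attrs["fs"] = float(recording.fs)
        d.attrs["units"] = "uV"
    recording.channel_table.to_csv(path / "channels.tsv", sep="\t", index=False)
    events.table.to_csv(path / "events.tsv", sep="\t", index=False)
    return path


def read_session(path: str | Path) -> tuple[Recording, TaskEvents]:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    h5 = path / "data.h5"
    if not h5.exists():
        raise SessionFormatError(f"no data.h5 under {path}")
    with h5py.File(h5, "r") as f:
        if "data" not in f:
            raise SessionFormatError("data.h5 lacks dataset 'data'")
        data = f["data"][()]
        fs = float(f["data"].attrs["fs"])
    channels = pd.read_csv(path / "channels.tsv", sep="\t")
    ev = pd.read_csv(path / "events.tsv", sep="\t")
    recording = Recording(data=data, fs=fs, channel_table=channels)
    events = TaskEvents(ev)
    return recording, events


def validate_session(path: str | Path) -> dict:
    """Check invariants of an on-disk session; return a summary dict."""
    rec, ev = read_session(path)
    n_move = len(ev.movement_epochs())
    n_rest = len(ev.of_type("rest"))
    return {
        "n_channels": rec.n_channels,
        "n_seeg": int((rec.channel_table["kind"] == "seeg").sum()),
        "n_emg": int((rec.channel_table["kind"] == "emg").sum()),
        "n_samples": rec.n_samples,
        "fs": rec.fs,
        "duration_s": rec.duration,
        "n_movement_epochs": n_move,
        "n_rest_epochs": n_rest,
    }
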