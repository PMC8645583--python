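"""Recordings, event tables and standard-format I/O.

A :class:`Recording` is a continuous multichannel EEG signal in microvolts
with its sampling rate, ordered 10-20 channel labels and an attached event
table.  Signals travel as EDF files; events travel as a sidecar TSV with
columns ``onset_s`` and ``label`` (0-based seconds from the first sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _edf
from .montage import DEFAULT_EXCLUDED, STANDARD_64, Montage

__all__ = [
    "EventList",
    "Recording",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "exclude_channels",
    "EVENT_LABELS",
]

EVENT_LABELS = frozenset({"eyes_open", "eyes_closed", "stim", "session_boundary"})


@dataclass(frozen=True)
class EventList:
    """Ordered event markers: onset in seconds from recording start + label."""

    onsets: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.onsets.ndim != 1 or len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must be 1-D and equal length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if np.any(self.onsets < 0):
            raise ValueError("event onsets must be non-negative")
        bad = set(self.labels) - EVENT_LABELS
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)

    def select(self, label: str) -> np.ndarray:
        """Onsets of all events carrying ``label``."""
        mask = np.array([l == label for l in self.labels], dtype=bool)
        return self.onsets[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "label": list(self.labels)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        return cls(df["onset_s"].to_numpy(dtype=float), tuple(df["label"]))

    @classmethod
    def empty(cls) -> "EventList":
        return cls(np.empty(0), ())


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in µV with events and montage context."""

    data: np.ndarray                 # channels x samples, µV
    fs: float                        # Hz
    channels: tuple[str, ...]
    events: EventList = field(default_factory=EventList.empty)
    reference: str | None = None
    montage: Montage = STANDARD_64

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if data.shape[0] != len(self.channels):
            raise ValueError("data row count must equal channel label count")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(data)):
            raise ValueError("signal contains NaN or infinite samples")
        if len(self.events) and np.max(self.events.onsets) >= self.duration:
            raise ValueError("event onset beyond recording duration")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds (time is 0-based from the first sample)."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


def write_events(events: EventList, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    if not {"onset_s", "label"} <= set(df.columns):
        raise ValueError("event table must have columns onset_s and label")
    return EventList.from_frame(df)


def write_recording(rec: Recording, path, events_path=None) -> None:
    """Write an EDF signal file plus (optionally) the TSV event sidecar.

    The per-channel physical range is chosen to cover the signal exactly, so
    large artifact excursions are represented rather than clipped; values the
    EDF header cannot express raise an error.
    """
    _edf.write_edf(path, rec.data, rec.fs, list(rec.channels))
    if events_path is not None:
        write_events(rec.events, events_path)


def read_recording(path, events_path=None, montage: Montage = STANDARD_64,
                   reference: str | None = "Cz") -> Recording:
    """Read an EDF file (+ TSV events) into a validated :class:`Recording`.

    Channel labels absent from the montage trigger a warning but are kept;
    mixed per-channel sampling rates are a format error.
    """
    data, fs, labels = _edf.read_edf(path)
    unknown = [l for l in labels if l not in montage]
    if unknown:
        warnings.warn(
            f"channels not in montage (kept): {unknown}", stacklevel=2
        )
    events = read_events(events_path) if events_path is not None else EventList.empty()
    ref = reference if reference in labels else None
    return Recording(data=data, fs=fs, channels=tuple(labels), events=events,
                     reference=ref, montage=montage)


def exclude_channels(rec: Recording, labels=DEFAULT_EXCLUDED) -> Recording:
    """Drop the named channels (default: HMD-blocked frontals + mastoids).

    Labels not present in the recording are ignored (already absent); labels
    outside the montage are rejected; removing every channel is an error.
    """
    labels = tuple(labels)
    bad = [l for l in labels if l not in rec.montage]
    if bad:
        raise KeyError(f"labels not in montage: {bad}")
    drop = {l for l in labels if l in rec.channels}
    keep = [i for i, l in enumerate(rec.channels) if l not in drop]
    if not keep:
        raise ValueError("cannot exclude all channels")
    return replace(
        rec,
        data=rec.data[keep],
        channels=tuple(rec.channels[i] for i in keep),
        reference=rec.reference if rec.reference not in drop else None,
    )
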