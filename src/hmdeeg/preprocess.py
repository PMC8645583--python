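"""Deterministic signal conditioning shared by both analysis branches.

All filters are Butterworth designs applied forward and backward
(``sosfiltfilt``), so the net phase response is zero and the effective
magnitude order doubles.  Epoch windows are half-open ``[tmin, tmax)`` in
seconds relative to the event onset; the onset sample belongs to the
post-stimulus side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .io import Recording

__all__ = [
    "EpochSet",
    "highpass_zero_phase",
    "bandstop_zero_phase",
    "common_average_reference",
    "epoch",
    "baseline_correct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochSet:
    """Trials x channels x samples cut around events, with metadata."""

    data: np.ndarray
    tmin: float
    tmax: float
    fs: float
    channels: tuple[str, ...]
    metadata: pd.DataFrame      # one row per trial (label, onset, ...)

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis must match channel labels")
        expected = int(round((self.tmax - self.tmin) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"sample count {self.data.shape[2]} != "
                f"round((tmax - tmin) * fs) = {expected}")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event onset."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"required electrode missing: {label!r}") from None

    def get_channel(self, label: str) -> np.ndarray:
        """trials x samples for one electrode."""
        return self.data[:, self.channel_index(label), :]


def _filtfilt_rec(rec: Recording, sos: np.ndarray) -> Recording:
    return rec.with_data(sosfiltfilt(sos, rec.data, axis=1))


def highpass_zero_phase(rec: Recording, cutoff: float = 0.1,
                        order: int = 3) -> Recording:
    """Forward-backward Butterworth high-pass; removes DC with zero net
    phase shift (default 0.1 Hz, third order)."""
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return _filtfilt_rec(rec, sos)


def bandstop_zero_phase(rec: Recording, band: tuple[float, float] = (48.0, 52.0),
                        order: int = 3) -> Recording:
    """Forward-backward Butterworth band-stop (default 48-52 Hz notch for
    mains removal in the SEP branch)."""
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    sos = butter(order, (lo, hi), btype="bandstop", fs=rec.fs, output="sos")
    return _filtfilt_rec(rec, sos)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract, per sample, the mean across all channels present.

    The original recording reference should be present as its explicit
    all-zero channel so it is re-referenced correctly.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="CAR")


def epoch(rec: Recording, label: str, tmin: float, tmax: float) -> EpochSet:
    """Cut one trial per event carrying ``label`` over ``[tmin, tmax)``.

    Trials extending beyond the recording are dropped (and counted in the
    log), never zero-padded.  No matching events, or none surviving, is an
    error.
    """
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin")
    onsets = rec.events.select(label)
    if onsets.size == 0:
        raise ValueError(f"no events labelled {label!r}")
    n_win = int(round((tmax - tmin) * rec.fs))
    starts = np.round((onsets + tmin) * rec.fs).astype(int)
    ok = (starts >= 0) & (starts + n_win <= rec.n_samples)
    dropped = int(np.count_nonzero(~ok))
    if dropped:
        logger.info("epoch(%r): dropped %d boundary trial(s)", label, dropped)
    if not np.any(ok):
        raise ValueError(f"all {label!r} trials fall outside the recording")
    trials = np.stack([rec.data[:, s:s + n_win] for s in starts[ok]])
    meta = pd.DataFrame({"onset_s": onsets[ok], "label": label})
    return EpochSet(data=trials, tmin=tmin, tmax=tmax, fs=rec.fs,
                    channels=rec.channels, metadata=meta)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.050, -0.010),
                     statistic: str = "median") -> EpochSet:
    """Subtract a pre-stimulus summary from every sample of each trial.

    The default window [-50, -10) ms is the first 40 ms of a -50 ms
    pre-stimulus span; the default statistic is the median, robust to
    stimulation-artifact ringing near the onset.
    """
    w0, w1 = window
    if not (epochs.tmin <= w0 < w1 <= 0):
        raise ValueError("baseline window must lie within [tmin, 0)")
    i0 = int(round((w0 - epochs.tmin) * epochs.fs))
    i1 = int(round((w1 - epochs.tmin) * epochs.fs))
    if i1 <= i0:
        raise ValueError("baseline window contains no samples")
    seg = epochs.data[:, :, i0:i1]
    if statistic == "median":
        base = np.median(seg, axis=2, keepdims=True)
    elif statistic == "mean":
        base = seg.mean(axis=2, keepdims=True)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    return replace(epochs, data=epochs.data - base)
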