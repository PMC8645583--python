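"""Frequency-domain branch: trial spectra, relative spectrograms, alpha
summaries and differential artifact peaks.

The trial power spectrum is a bare rectangular-window FFT over the full
epoch with one-sided scaling ``P_k = (2/N^2) |X_k|^2`` for interior bins
(no doubling at DC or Nyquist), so a sinusoid of amplitude *a* at a bin
frequency carries power a²/2 (µV²) at that bin.  Across-trial summaries
use the median throughout, robust to occasional artifact-laden trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import STANDARD_64, Montage
from .preprocess import EpochSet

__all__ = [
    "SpectrumSet",
    "RelativeSpectrogram",
    "AlphaSummary",
    "power_spectrum",
    "sliding_window_spectra",
    "median_spectrum",
    "sliding_relative_spectrogram",
    "alpha_summary",
    "differential_peaks",
]


@dataclass(frozen=True)
class SpectrumSet:
    """Per-trial, per-channel one-sided power spectra on a shared axis."""

    freqs: np.ndarray                 # Hz, strictly increasing
    power: np.ndarray                 # trials x channels x bins, µV²
    channels: tuple[str, ...]
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.power.ndim != 3 or self.power.shape[1] != len(self.channels):
            raise ValueError("power must be trials x channels x bins")
        if self.power.shape[2] != self.freqs.size:
            raise ValueError("bin axis must match frequency axis")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def select(self, fmin: float, fmax: float) -> "SpectrumSet":
        """Restrict to bins with fmin <= f <= fmax."""
        m = (self.freqs >= fmin) & (self.freqs <= fmax)
        return SpectrumSet(self.freqs[m], self.power[:, :, m],
                           self.channels, self.metadata)

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectra") from None


@dataclass(frozen=True)
class RelativeSpectrogram:
    """Across-trial median eyes-closed / eyes-open power ratio, resolved
    over sliding-window time within the trial."""

    times: np.ndarray                 # window centers, s within trial
    freqs: np.ndarray                 # Hz
    ratio: np.ndarray                 # times x channels x bins
    channels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.ratio.shape != (self.times.size, len(self.channels),
                                self.freqs.size):
            raise ValueError("ratio must be times x channels x bins")
        if np.any(self.ratio <= 0):
            raise ValueError("relative power must be strictly positive")


@dataclass(frozen=True)
class AlphaSummary:
    """Subject-specific alpha description: peak frequency, ±2 Hz band and
    per-electrode mean relative power in that band."""

    peak_freq: float
    band: tuple[float, float]
    topography: pd.Series             # index: electrode labels


def _onesided_power(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window power of ``data`` (..., samples)."""
    n = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    power = np.abs(spec) ** 2 * (2.0 / n ** 2)
    power[..., 0] /= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / fs), power


def power_spectrum(epochs: EpochSet) -> SpectrumSet:
    """Full-epoch FFT power per trial and channel (bin spacing 1/epoch)."""
    if epochs.n_trials == 0:
        raise ValueError("no trials to transform")
    freqs, power = _onesided_power(epochs.data, epochs.fs)
    return SpectrumSet(freqs, power, epochs.channels,
                       epochs.metadata.reset_index(drop=True))


def sliding_window_spectra(epochs: EpochSet, window_s: float = 2.5,
                           step_s: float = 0.25) -> SpectrumSet:
    """Spectra of all sliding windows of all trials, flattened along the
    trial axis (trial-major, window-minor); used to build baselines."""
    freqs, spec, _ = _sliding_spectra(epochs, window_s, step_s)
    n_tr, n_win, n_ch, n_bins = spec.shape
    return SpectrumSet(freqs, spec.reshape(n_tr * n_win, n_ch, n_bins),
                       epochs.channels)


def _sliding_spectra(epochs: EpochSet, window_s: float, step_s: float):
    """(freqs, trials x windows x channels x bins, window-center times)."""
    win = int(round(window_s * epochs.fs))
    step = int(round(step_s * epochs.fs))
    if win > epochs.n_samples:
        raise ValueError("window longer than epoch")
    starts = np.arange(0, epochs.n_samples - win + 1, step)
    segs = np.stack([epochs.data[:, :, s:s + win] for s in starts], axis=1)
    freqs, power = _onesided_power(segs, epochs.fs)
    centers = epochs.tmin + (starts + win / 2.0) / epochs.fs
    return freqs, power, centers


def median_spectrum(specs: SpectrumSet) -> np.ndarray:
    """Element-wise median across trials -> channels x bins (µV²)."""
    if specs.n_trials == 0:
        raise ValueError("empty spectrum set")
    return np.median(specs.power, axis=0)


def sliding_relative_spectrogram(closed: EpochSet, open_baseline: SpectrumSet,
                                 window_s: float = 2.5,
                                 step_s: float = 0.25) -> RelativeSpectrogram:
    """Time-resolved eyes-closed power relative to the eyes-open baseline.

    Each 2.5-s window (step 0.25 s) of every closed trial is divided
    bin-wise by the across-trial/window median eyes-open spectrum (built
    with :func:`sliding_window_spectra` at the same window length); the
    result is the across-trial median ratio per (time, channel, bin).
    """
    freqs, power, centers = _sliding_spectra(closed, window_s, step_s)
    if open_baseline.freqs.size != freqs.size or \
            not np.allclose(open_baseline.freqs, freqs):
        raise ValueError("baseline was not computed with the same window "
                         "length as the closed-trial windows")
    baseline = median_spectrum(open_baseline)      # channels x bins
    if np.any(baseline == 0):
        raise ValueError("degenerate baseline: zero power in some bins")
    ratio = np.median(power / baseline[None, None], axis=0)  # win x ch x bins
    return RelativeSpectrogram(times=centers, freqs=freqs, ratio=ratio,
                               channels=closed.channels)


def alpha_summary(rel: RelativeSpectrogram,
                  search: tuple[float, float] = (7.0, 14.0),
                  montage: Montage = STANDARD_64,
                  band_halfwidth: float = 2.0) -> AlphaSummary:
    """Individual alpha peak and its ±2 Hz band topography.

    The peak is the argmax, over the search range, of the relative power
    averaged over window times and occipital electrodes; the topography is
    each electrode's mean ratio over the band and all window times.
    """
    in_range = (rel.freqs >= search[0]) & (rel.freqs <= search[1])
    if not np.any(in_range):
        raise ValueError("search range outside the frequency axis")
    occ = [i for i, c in enumerate(rel.channels)
           if c in montage and montage.region(c) == "occipital"]
    if not occ:
        raise ValueError("no occipital electrodes present")
    curve = rel.ratio[:, occ, :].mean(axis=(0, 1))[in_range]
    freqs = rel.freqs[in_range]
    if np.ptp(curve) < 1e-12:
        warnings.warn("flat relative spectrum in the alpha search range; "
                      "using the range midpoint", stacklevel=2)
        peak = float(freqs[len(freqs) // 2])
    else:
        peak = float(freqs[np.argmax(curve)])
    band = (peak - band_halfwidth, peak + band_halfwidth)
    in_band = (rel.freqs >= band[0]) & (rel.freqs <= band[1])
    topo = rel.ratio[:, :, in_band].mean(axis=(0, 2))
    return AlphaSummary(peak_freq=peak, band=band,
                        topography=pd.Series(topo, index=list(rel.channels)))


def differential_peaks(median_vr: np.ndarray, median_novr: np.ndarray,
                       sig_map, min_freq: float, max_freq: float,
                       merge_bins: int = 2) -> pd.DataFrame:
    """Condition-specific spectral peaks from the significance map.

    Bins in ``[min_freq, max_freq]`` significant on any electrode are
    grouped (bins within ``merge_bins`` of each other merge, absorbing
    leakage splatter); each group reports the bin maximizing the
    electrode-median VR/No-VR power ratio, that ratio, and how many
    electrodes are significant there.  Sorted by ratio, descending.
    """
    freqs = np.asarray(sig_map.freqs)
    rejected = np.asarray(sig_map.rejected)
    if median_vr.shape != median_novr.shape or \
            median_vr.shape != rejected.shape:
        raise ValueError("spectra and significance map shapes differ")
    sel = (freqs >= min_freq) & (freqs <= max_freq)
    any_sig = rejected.any(axis=0) & sel
    idx = np.flatnonzero(any_sig)
    rows = []
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > merge_bins) + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(median_novr > 0, median_vr / median_novr, np.inf)
        for group in np.split(idx, splits):
            med = np.median(ratio[:, group], axis=0)
            best = group[np.argmax(med)]
            rows.append({
                "freq_hz": float(freqs[best]),
                "ratio": float(np.median(ratio[:, best])),
                "n_electrodes_significant": int(rejected[:, best].sum()),
            })
    out = pd.DataFrame(rows, columns=["freq_hz", "ratio",
                                      "n_electrodes_significant"])
    return out.sort_values("ratio", ascending=False, ignore_index=True)
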