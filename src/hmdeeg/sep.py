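"""Time-domain branch: somatosensory evoked potential component analysis.

Per-epoch N20 and P37 latency/amplitude are extracted at the electrodes
where median-nerve SEPs are expressed (C6 and CP4): N20 is the trace
minimum in its search window, P37 the maximum in its window, ties broken
toward the earliest sample.  The single-trial signal-to-noise ratio
divides the absolute amplitude by the interquartile range of the amplitude
distribution across epochs of the same condition.  Summaries use the
median with a normal-approximation standard error of the median,
SE = 1.2533 sd / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .preprocess import EpochSet
from .stats import fdr_bh, rank_sum_test

__all__ = [
    "SEP_ELECTRODES",
    "COMPONENT_WINDOWS",
    "median_sep_waveform",
    "extract_components",
    "component_snr",
    "summarize_components",
    "compare_conditions",
]

SEP_ELECTRODES = ("C6", "CP4")

#: Search windows in seconds post-stimulus and expected polarity.
#: Conventional windows around the components' nominal latencies.
COMPONENT_WINDOWS: dict[str, tuple[float, float, int]] = {
    "N20": (0.015, 0.025, -1),
    "P37": (0.030, 0.045, +1),
}

_SE_MEDIAN_FACTOR = 1.2533      # sqrt(pi/2): SE of a median, normal approx


def _median_se(values: np.ndarray) -> float:
    return _SE_MEDIAN_FACTOR * np.std(values, ddof=1) / np.sqrt(values.size)


@dataclass(frozen=True)
class _Window:
    i0: int
    i1: int


def _window_indices(epochs: EpochSet, t0: float, t1: float) -> _Window:
    if not (epochs.tmin <= t0 < t1 <= epochs.tmax):
        raise ValueError(f"component window [{t0}, {t1}) outside epoch "
                         f"[{epochs.tmin}, {epochs.tmax})")
    i0 = int(round((t0 - epochs.tmin) * epochs.fs))
    i1 = int(round((t1 - epochs.tmin) * epochs.fs))
    return _Window(i0, i1)


def median_sep_waveform(epochs: EpochSet, electrode: str,
                        display_highpass_hz: float | None = None) -> pd.DataFrame:
    """Across-epoch median waveform with per-timepoint standard error.

    Columns: ``time_ms``, ``median_uv``, ``se_uv``.  For display export a
    10 Hz zero-phase high-pass (third-order Butterworth) may be applied to
    the epochs first; it is never part of the measurement path.
    """
    traces = epochs.get_channel(electrode)          # trials x samples
    if display_highpass_hz is not None:
        sos = butter(3, display_highpass_hz, btype="highpass",
                     fs=epochs.fs, output="sos")
        traces = sosfiltfilt(sos, traces, axis=1)
    med = np.median(traces, axis=0)
    if traces.shape[0] > 1:
        se = _SE_MEDIAN_FACTOR * traces.std(axis=0, ddof=1) \
            / np.sqrt(traces.shape[0])
    else:
        se = np.zeros_like(med)
    return pd.DataFrame({"time_ms": epochs.times * 1000.0,
                         "median_uv": med, "se_uv": se})


def extract_components(epochs: EpochSet, electrode: str,
                       windows: dict[str, tuple[float, float, int]] | None = None,
                       ) -> pd.DataFrame:
    """Per-epoch component latency and amplitude at one electrode.

    Returns a table with one row per (epoch, component): columns ``epoch``,
    ``electrode``, ``component``, ``latency_ms``, ``amplitude_uv``.  The
    N20 amplitude is <= 0 and the P37 amplitude >= 0 by construction only
    on noise-free input; on real data the extremum simply is what it is.
    """
    windows = windows if windows is not None else COMPONENT_WINDOWS
    traces = epochs.get_channel(electrode)
    frames = []
    for name, (t0, t1, polarity) in windows.items():
        win = _window_indices(epochs, t0, t1)
        seg = traces[:, win.i0:win.i1]
        if polarity < 0:
            idx = np.argmin(seg, axis=1)
        else:
            idx = np.argmax(seg, axis=1)
        amp = seg[np.arange(seg.shape[0]), idx]
        lat = (epochs.tmin + (win.i0 + idx) / epochs.fs) * 1000.0
        frames.append(pd.DataFrame({
            "epoch": np.arange(seg.shape[0]),
            "electrode": electrode,
            "component": name,
            "latency_ms": lat,
            "amplitude_uv": amp,
        }))
    return pd.concat(frames, ignore_index=True)


def component_snr(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the per-epoch ``snr`` column within one condition.

    For each (electrode, component) group the noise scale is the
    interquartile range (linear-interpolation quantiles) of the amplitude
    distribution across epochs; snr_i = |amplitude_i| / IQR.  A zero IQR
    (possible only for degenerate synthetic input) is an error.
    """
    required = {"electrode", "component", "amplitude_uv"}
    if not required <= set(table.columns):
        raise ValueError(f"component table must have columns {sorted(required)}")
    out = table.copy()
    out["snr"] = np.nan
    for (_, _), grp in out.groupby(["electrode", "component"], sort=False):
        if len(grp) < 4:
            raise ValueError("need >= 4 epochs to estimate the IQR noise scale")
        amps = grp["amplitude_uv"].to_numpy()
        q1, q3 = np.percentile(amps, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            raise ValueError("degenerate amplitude distribution (IQR = 0)")
        out.loc[grp.index, "snr"] = np.abs(amps) / iqr
    return out


def summarize_components(table: pd.DataFrame) -> pd.DataFrame:
    """Median ± SE of latency and SNR per (electrode, component)."""
    rows = []
    for (elec, comp), grp in table.groupby(["electrode", "component"],
                                           sort=False):
        lat = grp["latency_ms"].to_numpy()
        snr = grp["snr"].to_numpy()
        rows.append({
            "electrode": elec, "component": comp, "n_epochs": len(grp),
            "latency_median_ms": float(np.median(lat)),
            "latency_se_ms": float(_median_se(lat)),
            "snr_median": float(np.median(snr)),
            "snr_se": float(_median_se(snr)),
        })
    return pd.DataFrame(rows)


def compare_conditions(vr: pd.DataFrame, novr: pd.DataFrame,
                       q: float = 0.001) -> pd.DataFrame:
    """VR vs. No-VR rank-sum tests on per-epoch latency and SNR.

    One test per (electrode, component, measure in {latency, snr}) — eight
    tests for the default two electrodes x two components — corrected as
    one BH family at level ``q`` (default 0.001).  Missing component rows
    in either table are an error.
    """
    for tbl, name in ((vr, "vr"), (novr, "novr")):
        if "snr" not in tbl.columns:
            raise ValueError(f"{name} table lacks the snr column; run "
                             "component_snr first")
    keys_vr = set(map(tuple, vr[["electrode", "component"]].drop_duplicates()
                      .itertuples(index=False)))
    keys_novr = set(map(tuple, novr[["electrode", "component"]]
                        .drop_duplicates().itertuples(index=False)))
    if keys_vr != keys_novr:
        raise ValueError("electrode/component sets differ between conditions")
    if not keys_vr:
        raise ValueError("empty component tables")
    rows = []
    for elec, comp in sorted(keys_vr):
        g_vr = vr[(vr.electrode == elec) & (vr.component == comp)]
        g_novr = novr[(novr.electrode == elec) & (novr.component == comp)]
        for measure, col in (("latency", "latency_ms"), ("snr", "snr")):
            stat, p = rank_sum_test(g_vr[col].to_numpy(),
                                    g_novr[col].to_numpy())
            rows.append({"electrode": elec, "component": comp,
                         "measure": measure, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    mask, threshold = fdr_bh(out["p"].to_numpy(), q)
    out["rejected"] = mask
    out.attrs["q"] = q
    out.attrs["bh_threshold"] = threshold
    return out
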