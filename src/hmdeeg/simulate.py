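"""Synthetic paired VR / No-VR EEG sessions.

Generates the two benchmark tasks — the eyes-open/eyes-closed (alpha
blockade) task and the median-nerve SEP task — with the statistical
structure the analysis probes:

* 1/f^γ background EEG (spectrally shaped white noise, exact target PSD),
* occipitally weighted alpha whose amplitude switches with eye state,
* 50 Hz mains interference plus decaying harmonics,
* optional HMD artifact line profiles ("oculus_like": 52 and 90 Hz plus
  harmonics and extra lines above 100 Hz; "vive_like": clean) and an
  optional environmental 87 Hz line in No-VR sessions,
* jittered median-nerve stimulation trains with N20/P37 Gaussian component
  templates concentrated at C6/CP4 plus a stimulation-artifact spike.

Mains and environmental lines use one random phase per line shared across
channels and deterministic per-channel coupling weights, so after
common-average referencing their band power is identically distributed
across independently seeded sessions (a true null for condition tests).
HMD lines get seeded random per-channel weights and phases: they appear in
one condition only and are the signal the benchmark must detect.

The recording is returned referenced to Cz (the Cz row is the explicit
all-zero reference channel), mirroring the acquisition montage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import EventList, Recording
from .montage import STANDARD_64, TEST_19_LABELS

__all__ = [
    "SpectralLine",
    "ArtifactProfile",
    "SEPComponent",
    "SEPConfig",
    "GeneratorConfig",
    "OCULUS_LIKE",
    "VIVE_LIKE",
    "ENV_87",
    "PROFILES",
    "get_profile",
    "test_preset",
    "simulate_background",
    "inject_lines",
    "simulate_berger_session",
    "simulate_sep_session",
]


@dataclass(frozen=True)
class SpectralLine:
    """One narrowband interference line: base frequency, RMS amplitude,
    number of additional harmonics and their per-step RMS decay factor."""

    freq: float            # Hz
    rms: float             # µV
    harmonics: int = 0
    harmonic_decay: float = 0.5

    def expand(self, nyquist: float) -> list[tuple[float, float]]:
        """(frequency, rms) for the base line and its harmonics below
        Nyquist; harmonics above Nyquist are silently omitted."""
        out = []
        for k in range(self.harmonics + 1):
            f = self.freq * (k + 1)
            if f >= nyquist:
                continue
            out.append((f, self.rms * self.harmonic_decay ** k))
        return out


@dataclass(frozen=True)
class ArtifactProfile:
    """Named set of spectral lines with a per-channel coupling-weight range
    (weights are drawn per line, per channel, seeded)."""

    name: str
    lines: tuple[SpectralLine, ...]
    weight_range: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self):
        if any(l.rms < 0 for l in self.lines):
            raise ValueError("line amplitudes must be non-negative")

    def max_base_freq(self) -> float:
        return max((l.freq for l in self.lines), default=0.0)


# Built-in profiles.  The Oculus-like HMD leaves lines at 52 and 90 Hz plus
# harmonics and extra high-frequency lines; the Vive-like HMD is spectrally
# clean; "env_87" models an environmental 87 Hz line seen without the HMD.
OCULUS_LIKE = ArtifactProfile("oculus_like", (
    SpectralLine(52.0, 1.5, harmonics=2, harmonic_decay=0.5),
    SpectralLine(90.0, 3.0, harmonics=2, harmonic_decay=0.5),
    SpectralLine(137.0, 2.0),
    SpectralLine(211.0, 2.0),
))
VIVE_LIKE = ArtifactProfile("vive_like", ())
ENV_87 = ArtifactProfile("env_87", (SpectralLine(87.0, 1.0),))

PROFILES = {p.name: p for p in (OCULUS_LIKE, VIVE_LIKE, ENV_87)}
PROFILES["none"] = None


def get_profile(name: str | None) -> ArtifactProfile | None:
    if name is None:
        return None
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown artifact profile {name!r}; "
                         f"choose from {sorted(PROFILES)}") from None


@dataclass(frozen=True)
class SEPComponent:
    """Gaussian-windowed evoked-component template."""

    name: str
    polarity: int          # -1 negative (N20), +1 positive (P37)
    latency_ms: float
    width_ms: float        # FWHM of the Gaussian bump
    amplitude_uv: float    # peak magnitude, µV


@dataclass(frozen=True)
class SEPConfig:
    n_sessions: int = 5
    n_stim_per_session: int = 100
    isi_s: tuple[float, float] = (0.2, 0.5)   # 2-5 Hz stimulation rate
    components: tuple[SEPComponent, ...] = (
        SEPComponent("N20", -1, 20.0, 5.0, 2.0),
        SEPComponent("P37", +1, 37.0, 10.0, 2.5),
    )
    artifact_uv: float = 50.0     # stimulation-artifact spike at t = 0
    session_gap_s: float = 2.0

    def __post_init__(self):
        for c in self.components:
            if not 0 < c.latency_ms / 1000.0 < self.isi_s[0]:
                raise ValueError(
                    f"component {c.name}: latency must be positive and "
                    f"shorter than the minimum inter-stimulus interval")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of one simulated subject/session pair."""

    fs: float = 5000.0
    channels: tuple[str, ...] = tuple(STANDARD_64.labels)
    n_trials_per_task: int = 50
    trial_s: float = 10.0
    background_exponent: float = 1.0     # 1/f^γ slope
    background_scale: float = 10.0       # µV RMS
    alpha_freq: float = 10.0             # Hz
    alpha_jitter: float = 1.0            # per-subject peak jitter span, Hz
    alpha_gain_closed: float = 6.0       # µV at the occipital maximum
    alpha_gain_open: float = 1.0
    mains_freq: float = 50.0
    mains_rms: float = 5.0               # µV
    mains_harmonics: int = 2             # 100 and 150 Hz; higher harmonics
                                         # would fall below the 1/f floor
    mains_harmonic_decay: float = 0.5
    hmd_profile: ArtifactProfile | None = None
    env_profile: ArtifactProfile | None = None   # applied in No-VR only
    sep: SEPConfig = field(default_factory=SEPConfig)
    seed: int = 0

    def __post_init__(self):
        if self.alpha_gain_closed < self.alpha_gain_open:
            raise ValueError("alpha_gain_closed must be >= alpha_gain_open "
                             "(equality models the no-effect null)")
        top = self.mains_freq
        for prof in (self.hmd_profile, self.env_profile):
            if prof is not None:
                top = max(top, prof.max_base_freq())
        if self.fs <= 2 * top:
            raise ValueError("fs must exceed twice the highest injected "
                             "base line frequency")
        missing = [c for c in self.channels if c not in STANDARD_64]
        if missing:
            raise ValueError(f"channels not in montage: {missing}")


def test_preset(**overrides) -> GeneratorConfig:
    """Reduced-scale conditions for fast runs: 19 channels, 500 Hz,
    10 trials per task, 2 SEP sessions of 25 stimulations."""
    kw = dict(
        fs=500.0,
        channels=TEST_19_LABELS,
        n_trials_per_task=10,
        sep=SEPConfig(n_sessions=2, n_stim_per_session=25),
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


# ---------------------------------------------------------------- internals

def _label_hash_uniform(label: str) -> float:
    """Deterministic pseudo-uniform in [0, 1) from a channel label."""
    return zlib.crc32(label.encode()) / 2**32


def _mains_weights(channels) -> np.ndarray:
    """Fixed heterogeneous mains coupling, identical across sessions."""
    return np.array([0.5 + 1.0 * _label_hash_uniform(c) for c in channels])


def _alpha_weights(channels) -> np.ndarray:
    """Occipitally dominant spatial profile (Gaussian falloff from Oz),
    normalized to a maximum of 1."""
    ox, oy = STANDARD_64.position("Oz")
    w = np.array([
        np.exp(-((x - ox) ** 2 + (y - oy) ** 2) / (2 * 0.4 ** 2))
        for x, y in (STANDARD_64.position(c) for c in channels)
    ])
    return w / w.max()


def _sep_weights(channels) -> np.ndarray:
    """Component topography concentrated midway between C6 and CP4 over the
    right centro-parietal scalp, normalized to max 1."""
    (x1, y1), (x2, y2) = STANDARD_64.position("C6"), STANDARD_64.position("CP4")
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    w = np.array([
        np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.3 ** 2))
        for x, y in (STANDARD_64.position(c) for c in channels)
    ])
    return w / w.max()


def simulate_background(config: GeneratorConfig, n_channels: int,
                        duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise whose one-sided PSD follows 1/f^γ above 1 Hz.

    Implemented by spectral shaping: independent complex-Gaussian Fourier
    coefficients scaled to the target PSD, inverse-FFT'd, and normalized so
    the *expected* RMS equals ``background_scale`` (the normalization is
    analytic, not per-realization, so γ = 0 is exactly white noise).
    """
    gamma = config.background_exponent
    if gamma < 0:
        raise ValueError("background exponent must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * config.fs))
    if config.background_scale == 0:
        return np.zeros((n_channels, n))

    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    amp = np.zeros_like(freqs)
    amp[1:] = np.maximum(freqs[1:], 1.0) ** (-gamma / 2.0)   # flat below 1 Hz

    z = rng.standard_normal((n_channels, freqs.size)) \
        + 1j * rng.standard_normal((n_channels, freqs.size))
    spec = amp * z / np.sqrt(2.0)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = amp[-1] * z[:, -1].real        # Nyquist bin is real

    x = np.fft.irfft(spec, n=n, axis=1)
    # E[sum x^2] = (2*sum interior A^2 + A_nyq^2)/n  =>  expected RMS
    interior = amp[1:-1] if n % 2 == 0 else amp[1:]
    e_power = (2 * np.sum(interior ** 2)
               + (amp[-1] ** 2 if n % 2 == 0 else 0.0)) / n ** 2
    return x * (config.background_scale / np.sqrt(e_power))


def inject_lines(signal: np.ndarray, profile: ArtifactProfile | None, fs: float,
                 rng: np.random.Generator | None = None,
                 weights: np.ndarray | None = None,
                 common_phase: bool = False) -> np.ndarray:
    """Return ``signal`` plus the profile's sinusoidal lines (input unchanged).

    Base line frequencies at or above Nyquist are an error (they would
    alias); harmonics above Nyquist are dropped.  Phases are uniform random
    per line — per channel by default, shared across channels when
    ``common_phase`` is set.  ``weights`` overrides the per-channel coupling
    (otherwise drawn uniformly from the profile's weight range per line).
    """
    signal = np.array(signal, dtype=float, copy=True)
    if profile is None or not profile.lines:
        return signal
    nyq = fs / 2.0
    bad = [l.freq for l in profile.lines if l.freq >= nyq]
    if bad:
        raise ValueError(f"aliased line frequencies (>= fs/2): {bad}")
    rng = rng if rng is not None else np.random.default_rng(0)
    n_ch, n = signal.shape
    t = np.arange(n) / fs
    for line in profile.lines:
        for f, rms in line.expand(nyq):
            w = weights if weights is not None else \
                rng.uniform(*profile.weight_range, size=n_ch)
            amp = rms * np.sqrt(2.0)
            if common_phase:
                phase = np.full(n_ch, rng.uniform(0, 2 * np.pi))
            else:
                phase = rng.uniform(0, 2 * np.pi, size=n_ch)
            signal += (w * amp)[:, None] * np.sin(
                2 * np.pi * f * t[None, :] + phase[:, None])
    return signal


def _mains_profile(config: GeneratorConfig) -> ArtifactProfile:
    return ArtifactProfile("mains", (
        SpectralLine(config.mains_freq, config.mains_rms,
                     config.mains_harmonics, config.mains_harmonic_decay),))


def _apply_reference(data: np.ndarray, channels: tuple[str, ...],
                     reference: str = "Cz") -> tuple[np.ndarray, str | None]:
    """Re-express source signals against the recording reference: subtract
    the reference channel from every row and zero it (so it stays present,
    as required for correct common-average re-referencing)."""
    if reference not in channels:
        return data, None
    idx = channels.index(reference)
    data = data - data[idx][None, :]
    data[idx] = 0.0
    return data, reference


def _condition_code(condition: str) -> int:
    c = condition.strip().lower().replace("-", "").replace("_", "")
    if c == "vr":
        return 1
    if c in ("novr", "no"):
        return 0
    raise ValueError(f"condition must be 'VR' or 'No-VR', got {condition!r}")


def _slow_modulation(n: int, fs: float, rng: np.random.Generator,
                     knot_s: float = 1.0, depth: float = 0.4) -> np.ndarray:
    """Slow positive amplitude-modulation envelope (mean ~1)."""
    n_knots = max(int(np.ceil(n / fs / knot_s)) + 2, 2)
    knots = rng.standard_normal(n_knots)
    t = np.arange(n) / fs
    m = np.interp(t, np.arange(n_knots) * knot_s, knots)
    return np.clip(1.0 + depth * m, 0.2, 2.0)


def simulate_berger_session(config: GeneratorConfig, condition: str) -> Recording:
    """One eyes-open/eyes-closed session: ``n_trials_per_task`` trials of
    each eye state in seeded pseudo-random order, each ``trial_s`` long.

    Alpha is an amplitude-switched sinusoid at ``alpha_freq`` (occipital
    spatial profile, slow random amplitude modulation) whose gain is
    ``alpha_gain_closed`` during closed-eye trials and ``alpha_gain_open``
    otherwise.  Mains lines are always on; the HMD profile is applied only
    in the VR condition, the environmental profile only in No-VR.
    """
    cond = _condition_code(condition)
    rng = np.random.default_rng([config.seed, 1, cond])
    fs, n_ch = config.fs, len(config.channels)
    n_total = 2 * config.n_trials_per_task
    lead = 1.0
    duration = 2 * lead + n_total * config.trial_s
    n = int(round(duration * fs))

    states = ["eyes_open"] * config.n_trials_per_task \
        + ["eyes_closed"] * config.n_trials_per_task
    states = [states[i] for i in rng.permutation(n_total)]
    onsets = lead + np.arange(n_total) * config.trial_s

    data = simulate_background(config, n_ch, duration, rng)

    # eye-state-dependent alpha gain per sample
    gain = np.full(n, config.alpha_gain_open)
    for onset, state in zip(onsets, states):
        if state == "eyes_closed":
            i0 = int(round(onset * fs))
            i1 = int(round((onset + config.trial_s) * fs))
            gain[i0:i1] = config.alpha_gain_closed
    carrier = np.sin(2 * np.pi * config.alpha_freq * np.arange(n) / fs
                     + rng.uniform(0, 2 * np.pi))
    envelope = gain * _slow_modulation(n, fs, rng)
    data += np.outer(_alpha_weights(config.channels), carrier * envelope)

    data = inject_lines(data, _mains_profile(config), fs, rng,
                        weights=_mains_weights(config.channels),
                        common_phase=True)
    if cond == 1 and config.hmd_profile is not None:
        data = inject_lines(data, config.hmd_profile, fs, rng)
    if cond == 0 and config.env_profile is not None:
        data = inject_lines(data, config.env_profile, fs, rng,
                            weights=_mains_weights(config.channels),
                            common_phase=True)

    data, ref = _apply_reference(data, config.channels)
    events = EventList(onsets, tuple(states))
    return Recording(data=data, fs=fs, channels=config.channels,
                     events=events, reference=ref)


def simulate_sep_session(config: GeneratorConfig, condition: str) -> Recording:
    """One median-nerve SEP session: ``n_sessions`` blocks of
    ``n_stim_per_session`` stimulations with ISIs drawn uniformly from
    ``isi_s``.  Each stimulus adds the Gaussian component templates (right
    centro-parietal topography) plus a stimulation-artifact spike at t = 0.
    Neighboring responses overlap by design (ISI < analysis epoch)."""
    cond = _condition_code(condition)
    rng = np.random.default_rng([config.seed, 2, cond])
    fs, n_ch = config.fs, len(config.channels)
    sep = config.sep

    onsets, labels = [], []
    t = 1.0
    for _ in range(sep.n_sessions):
        onsets.append(t)
        labels.append("session_boundary")
        t += 0.5
        for _ in range(sep.n_stim_per_session):
            onsets.append(t)
            labels.append("stim")
            t += rng.uniform(*sep.isi_s)
        t += sep.session_gap_s
    duration = t + 1.0
    n = int(round(duration * fs))
    stim_samples = np.array([int(round(o * fs)) for o, l in zip(onsets, labels)
                             if l == "stim"])

    data = simulate_background(config, n_ch, duration, rng)
    data = inject_lines(data, _mains_profile(config), fs, rng,
                        weights=_mains_weights(config.channels),
                        common_phase=True)
    if cond == 1 and config.hmd_profile is not None:
        data = inject_lines(data, config.hmd_profile, fs, rng)
    if cond == 0 and config.env_profile is not None:
        data = inject_lines(data, config.env_profile, fs, rng,
                            weights=_mains_weights(config.channels),
                            common_phase=True)

    w_comp = _sep_weights(config.channels)
    for comp in sep.components:
        sigma = comp.width_ms / 1000.0 / 2.3548          # FWHM -> std
        half = int(round(4 * sigma * fs))
        lat = int(round(comp.latency_ms / 1000.0 * fs))
        tt = np.arange(-half, half + 1) / fs
        template = comp.polarity * comp.amplitude_uv * \
            np.exp(-tt ** 2 / (2 * sigma ** 2))
        for s in stim_samples:
            i0, i1 = s + lat - half, s + lat + half + 1
            if 0 <= i0 and i1 <= n:
                data[:, i0:i1] += np.outer(w_comp, template)

    if sep.artifact_uv:
        w_art = np.array([0.6 + 0.4 * _label_hash_uniform(c)
                          for c in config.channels])
        width = max(int(round(0.001 * fs)), 1)
        for s in stim_samples:
            data[:, s:s + width] += sep.artifact_uv * w_art[:, None]

    data, ref = _apply_reference(data, config.channels)
    events = EventList(np.asarray(onsets), tuple(labels))
    return Recording(data=data, fs=fs, channels=config.channels,
                     events=events, reference=ref)
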