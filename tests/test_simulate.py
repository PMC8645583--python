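"""Generator contracts: background spectrum, line injection, session
structure, seed determinism and spectral fidelity."""

import numpy as np
import pytest
from scipy.signal import welch

import hmdeeg as H
from hmdeeg.simulate import SpectralLine, _alpha_weights, simulate_background
from hmdeeg.spectral import median_spectrum, power_spectrum
from hmdeeg.preprocess import epoch

from conftest import make_epochs


def loglog_slope(x, fs, fmin=5.0, fmax=100.0):
    f, p = welch(x, fs=fs, nperseg=int(4 * fs))
    sel = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]


class TestBackground:
    def test_white_noise_limit(self):
        cfg = H.test_preset(background_exponent=0.0)
        x = simulate_background(cfg, 1, 120.0, np.random.default_rng(0))
        assert abs(loglog_slope(x[0], cfg.fs)) < 0.15

    def test_pink_noise_slope(self):
        cfg = H.test_preset()           # gamma = 1
        x = simulate_background(cfg, 1, 150.0, np.random.default_rng(1))
        assert abs(loglog_slope(x[0], cfg.fs) - (-1.0)) < 0.15

    def test_rms_matches_scale(self):
        cfg = H.test_preset()
        x = simulate_background(cfg, 4, 100.0, np.random.default_rng(2))
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(
            cfg.background_scale, rel=0.15)

    def test_zero_scale_gives_zeros(self):
        cfg = H.test_preset(background_scale=0.0)
        x = simulate_background(cfg, 2, 5.0, np.random.default_rng(0))
        assert np.all(x == 0)

    def test_negative_exponent_rejected(self):
        cfg = H.test_preset(background_exponent=-0.5)
        with pytest.raises(ValueError, match="exponent"):
            simulate_background(cfg, 1, 1.0, np.random.default_rng(0))


class TestInjectLines:
    def test_empty_profile_identity(self):
        x = np.random.default_rng(0).standard_normal((2, 100))
        out = H.inject_lines(x, H.VIVE_LIKE, 100.0)
        assert np.array_equal(out, x)
        out2 = H.inject_lines(x, None, 100.0)
        assert np.array_equal(out2, x)

    def test_sinusoid_power_closed_form(self):
        """A 50 Hz line of RMS a lands power a^2 in the 50 Hz bin."""
        a = 3.0
        fs, dur = 250.0, 10.0
        prof = H.ArtifactProfile("one", (SpectralLine(50.0, a),))
        sig = H.inject_lines(np.zeros((1, int(fs * dur))), prof, fs,
                             np.random.default_rng(0), weights=np.ones(1))
        spec = power_spectrum(make_epochs(sig[None], fs, ("Cz",)))
        i50 = np.argmin(np.abs(spec.freqs - 50.0))
        assert spec.power[0, 0, i50] == pytest.approx(a ** 2, rel=1e-9)
        others = np.delete(spec.power[0, 0], i50)
        assert others.max() < 1e-10

    def test_aliased_line_rejected(self):
        prof = H.ArtifactProfile("bad", (SpectralLine(300.0, 1.0),))
        with pytest.raises(ValueError, match="alias"):
            H.inject_lines(np.zeros((1, 100)), prof, 500.0)

    def test_oculus_lines_and_nothing_else(self):
        """Peak-enumeration oracle on a pure-profile signal."""
        fs, dur = 500.0, 10.0
        sig = H.inject_lines(np.zeros((3, int(fs * dur))), H.OCULUS_LIKE, fs,
                             np.random.default_rng(1))
        spec = power_spectrum(make_epochs(sig[None], fs, ("Cz", "C3", "C4")))
        total = spec.power[0].sum(axis=0)
        expected = set()
        for line in H.OCULUS_LIKE.lines:
            for f, _ in line.expand(fs / 2):
                expected.add(f)
        found = set(spec.freqs[total > 1e-6 * total.max()])
        assert found == expected


class TestBergerSession:
    def test_event_count_and_balance(self):
        cfg = H.test_preset(seed=3)
        rec = H.simulate_berger_session(cfg, "No-VR")
        assert len(rec.events) == 2 * cfg.n_trials_per_task
        assert len(rec.events.select("eyes_closed")) == cfg.n_trials_per_task
        assert len(rec.events.select("eyes_open")) == cfg.n_trials_per_task

    def test_seed_determinism(self):
        cfg = H.test_preset(seed=7, hmd_profile=H.OCULUS_LIKE)
        a = H.simulate_berger_session(cfg, "VR")
        b = H.simulate_berger_session(cfg, "VR")
        assert np.array_equal(a.data, b.data)
        assert a.events.labels == b.events.labels

    def test_reference_channel_is_zero(self):
        cfg = H.test_preset(seed=0)
        rec = H.simulate_berger_session(cfg, "No-VR")
        assert rec.reference == "Cz"
        assert np.all(rec.get_channel("Cz") == 0)

    def test_equal_gains_null_ratio_near_one(self):
        """No eye-state effect -> relative spectrum ~ 1 in the alpha band."""
        from hmdeeg.spectral import (sliding_relative_spectrogram,
                                     sliding_window_spectra)
        cfg = H.test_preset(seed=5, n_trials_per_task=15,
                          alpha_gain_closed=3.0, alpha_gain_open=3.0)
        rec = H.simulate_berger_session(cfg, "No-VR")
        from hmdeeg.report import preprocess_spectral
        rec = preprocess_spectral(rec)
        closed = epoch(rec, "eyes_closed", 0.0, cfg.trial_s)
        open_ = epoch(rec, "eyes_open", 0.0, cfg.trial_s)
        rel = sliding_relative_spectrogram(closed,
                                           sliding_window_spectra(open_))
        band = (rel.freqs >= 8) & (rel.freqs <= 13)
        avg = rel.ratio[:, :, band].mean()
        assert 0.8 < avg < 1.25

    def test_occipital_alpha_dominance_weights(self):
        w = _alpha_weights(("O1", "Oz", "Fp1", "F3"))
        assert w[0] > w[2] and w[1] > w[3]


class TestSepSession:
    def test_stim_event_count(self):
        cfg = H.test_preset(seed=1)
        rec = H.simulate_sep_session(cfg, "No-VR")
        n_expected = cfg.sep.n_sessions * cfg.sep.n_stim_per_session
        assert len(rec.events.select("stim")) == n_expected
        assert len(rec.events.select("session_boundary")) == cfg.sep.n_sessions

    def test_isi_range(self):
        cfg = H.test_preset(seed=2)
        rec = H.simulate_sep_session(cfg, "No-VR")
        stim = rec.events.select("stim")
        isis = np.diff(stim)
        isis = isis[isis < 1.0]       # within-session intervals only
        assert isis.min() >= cfg.sep.isi_s[0]
        assert isis.max() <= cfg.sep.isi_s[1]

    def test_noise_free_n20_peak_location(self):
        """With noise off, the C6 trace minimum sits on the template."""
        cfg = H.test_preset(
            seed=0, background_scale=0.0, mains_rms=0.0,
            sep=H.SEPConfig(n_sessions=1, n_stim_per_session=1,
                            artifact_uv=0.0))
        rec = H.simulate_sep_session(cfg, "No-VR")
        onset = rec.events.select("stim")[0]
        c6 = rec.get_channel("C6")
        i = np.argmin(c6)
        lat = i / rec.fs - onset
        assert abs(lat - 0.020) <= 1.0 / rec.fs

    def test_components_disabled_flat_response(self):
        cfg = H.test_preset(
            seed=4, background_scale=0.0, mains_rms=0.0,
            sep=H.SEPConfig(n_sessions=1, n_stim_per_session=5,
                            components=(), artifact_uv=0.0))
        rec = H.simulate_sep_session(cfg, "No-VR")
        assert np.allclose(rec.data, 0.0)


class TestSpectralFidelity:
    def test_every_line_recoverable_no_strays(self, berger_pair):
        """All configured lines appear within one bin of their nominal
        frequency; no unconfigured narrowband peak exceeds 5x the local
        spectral median (checked above the alpha range)."""
        vr, _, cfg = berger_pair
        # raw session: the generator contract precedes CAR attenuation
        spec = power_spectrum(epoch(vr, "eyes_open", 0.0, cfg.trial_s))
        med = median_spectrum(spec).sum(axis=0)
        freqs = spec.freqs
        df = freqs[1] - freqs[0]
        expected = [cfg.mains_freq * (k + 1)
                    for k in range(cfg.mains_harmonics + 1)
                    if cfg.mains_freq * (k + 1) < cfg.fs / 2]
        for line in cfg.hmd_profile.lines:
            expected += [f for f, _ in line.expand(cfg.fs / 2)]
        for f in expected:
            i = np.argmin(np.abs(freqs - f))
            local = np.median(med[max(i - 50, 0):i + 50])
            assert med[i] > 5 * local, f"line at {f} Hz not recovered"
        # stray-peak scan above 20 Hz, away from configured lines
        for i in range(np.searchsorted(freqs, 20.0), len(freqs)):
            if min(abs(freqs[i] - f) for f in expected) <= 2 * df:
                continue
            local = np.median(med[max(i - 50, 0):i + 50])
            assert med[i] <= 5 * local, f"stray peak at {freqs[i]} Hz"
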