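"""Spectrum scaling closed forms, relative spectrograms, alpha summaries
and differential-peak extraction."""

import numpy as np
import pytest

import hmdeeg as H
from hmdeeg.preprocess import epoch
from hmdeeg.report import preprocess_spectral, spectral_branch
from hmdeeg.spectral import (SpectrumSet, alpha_summary, differential_peaks,
                             median_spectrum, power_spectrum,
                             sliding_relative_spectrogram,
                             sliding_window_spectra, _sliding_spectra)
from hmdeeg.stats import SignificanceMap

from conftest import make_epochs


class TestPowerSpectrum:
    def test_zeros_give_zero_power(self):
        ep = make_epochs(np.zeros((2, 1, 100)), 100.0, ("Cz",))
        assert np.all(power_spectrum(ep).power == 0)

    def test_sinusoid_closed_form(self):
        """2 µV at 10 Hz, 10 s @ 250 Hz -> P(10 Hz) = 2.0 µV², rest ~ 0."""
        fs, dur, amp = 250.0, 10.0, 2.0
        t = np.arange(int(fs * dur)) / fs
        x = amp * np.sin(2 * np.pi * 10 * t + 0.7)
        spec = power_spectrum(make_epochs(x[None, None], fs, ("O1",)))
        i10 = np.argmin(np.abs(spec.freqs - 10.0))
        assert spec.power[0, 0, i10] == pytest.approx(amp ** 2 / 2, rel=1e-9)
        assert np.delete(spec.power[0, 0], i10).max() < 1e-10

    def test_axis_reaches_half_sampling_rate(self):
        """A 10-s trial at 5,000 Hz spans 0..2,500 Hz at 0.1 Hz spacing."""
        ep = make_epochs(np.zeros((1, 1, 50000)), 5000.0, ("Cz",))
        spec = power_spectrum(ep)
        assert spec.freqs[-1] == pytest.approx(2500.0)
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(0.1)

    def test_parseval(self):
        """Energy conservation for the one-sided scaling:
        sum_k P_k * N = sum_n x_n^2."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 2, 512))
        spec = power_spectrum(make_epochs(x, 256.0, ("Cz", "Pz")))
        lhs = spec.power.sum(axis=-1) * 512
        rhs = (x ** 2).sum(axis=-1)
        assert np.allclose(lhs, rhs, rtol=1e-6)


class TestMedianSpectrum:
    def test_single_trial_identity(self):
        rng = np.random.default_rng(1)
        spec = power_spectrum(make_epochs(
            rng.standard_normal((1, 2, 64)), 64.0, ("Cz", "Pz")))
        assert np.array_equal(median_spectrum(spec), spec.power[0])

    def test_outlier_robustness(self):
        freqs = np.array([1.0, 2.0])
        power = np.array([[[1.0, 1]], [[2.0, 2]], [[100.0, 100]]])
        spec = SpectrumSet(freqs, power, ("Cz",))
        assert np.allclose(median_spectrum(spec), 2.0)

    def test_between_min_and_max(self):
        rng = np.random.default_rng(2)
        spec = power_spectrum(make_epochs(
            rng.standard_normal((7, 1, 128)), 128.0, ("Cz",)))
        med = median_spectrum(spec)
        assert np.all(med <= spec.power.max(axis=0) + 1e-15)
        assert np.all(med >= spec.power.min(axis=0) - 1e-15)


class TestRelativeSpectrogram:
    def test_window_count_for_ten_second_trials(self):
        """floor((10 - 2.5)/0.25) + 1 = 31 window positions."""
        ep = make_epochs(np.zeros((1, 1, 5000)), 500.0, ("O1",))
        _, power, centers = _sliding_spectra(ep, 2.5, 0.25)
        assert power.shape[1] == 31
        assert centers[0] == pytest.approx(1.25)
        assert centers[-1] == pytest.approx(8.75)

    def test_null_converges_to_one(self):
        """Same-distribution conditions -> median ratio ~ 1."""
        rng = np.random.default_rng(3)
        fs, n_tr = 100.0, 32
        closed = make_epochs(rng.standard_normal((n_tr, 1, 1000)), fs, ("O1",))
        open_ = make_epochs(rng.standard_normal((n_tr, 1, 1000)), fs, ("O1",))
        rel = sliding_relative_spectrogram(closed,
                                           sliding_window_spectra(open_))
        time_avg = rel.ratio.mean(axis=0)
        assert 0.9 < np.median(time_avg) < 1.1
        assert np.mean((time_avg > 0.8) & (time_avg < 1.25)) > 0.9

    def test_amplitude_doubling_gives_ratio_four(self):
        """Power scales with amplitude squared."""
        fs, n = 100.0, 1000
        t = np.arange(n) / fs
        rng = np.random.default_rng(4)
        base = 1e-4 * rng.standard_normal((8, 1, n))    # tiny floor
        closed = make_epochs(
            base + 2.0 * np.sin(2 * np.pi * 10 * t), fs, ("O1",))
        open_ = make_epochs(
            base + 1.0 * np.sin(2 * np.pi * 10 * t), fs, ("O1",))
        rel = sliding_relative_spectrogram(closed,
                                           sliding_window_spectra(open_))
        i10 = np.argmin(np.abs(rel.freqs - 10.0))
        assert np.median(rel.ratio[:, 0, i10]) == pytest.approx(4.0, rel=0.01)

    def test_zero_baseline_rejected(self):
        closed = make_epochs(np.ones((2, 1, 500)), 100.0, ("O1",))
        open_ = make_epochs(np.zeros((2, 1, 500)), 100.0, ("O1",))
        with pytest.raises(ValueError, match="degenerate"):
            sliding_relative_spectrogram(closed,
                                         sliding_window_spectra(open_))


class TestAlphaSummary:
    @pytest.mark.parametrize("alpha_freq", [8.0, 10.0, 12.0])
    def test_peak_recovery(self, alpha_freq):
        cfg = H.test_preset(seed=13, n_trials_per_task=20,
                            alpha_freq=alpha_freq)
        rec = preprocess_spectral(H.simulate_berger_session(cfg, "No-VR"))
        closed = epoch(rec, "eyes_closed", 0.0, cfg.trial_s)
        open_ = epoch(rec, "eyes_open", 0.0, cfg.trial_s)
        rel = sliding_relative_spectrogram(closed,
                                           sliding_window_spectra(open_))
        summ = alpha_summary(rel)
        assert abs(summ.peak_freq - alpha_freq) <= 0.4 + 1e-9

    def test_occipital_dominant_topography(self, spectral_results):
        topo = spectral_results["alpha"]["novr"].topography
        occ = topo[[c for c in topo.index if c in ("O1", "O2")]].mean()
        frontal = topo[[c for c in topo.index
                        if c.startswith(("Fp", "F"))]].mean()
        assert occ > frontal

    def test_flat_ratio_warns_midpoint(self):
        freqs = np.arange(1.0, 20.0, 0.4)
        rel = H.RelativeSpectrogram(
            times=np.array([1.0]), freqs=freqs,
            ratio=np.ones((1, 1, freqs.size)), channels=("O1",))
        with pytest.warns(UserWarning, match="flat"):
            summ = alpha_summary(rel)
        sel = freqs[(freqs >= 7) & (freqs <= 14)]
        assert summ.peak_freq == sel[len(sel) // 2]


class TestDifferentialPeaks:
    @staticmethod
    def empty_map(freqs, n_ch):
        shape = (n_ch, freqs.size)
        return SignificanceMap(
            channels=tuple(f"C{i}" for i in range(n_ch)), freqs=freqs,
            p=np.ones(shape), statistic=np.zeros(shape),
            rejected=np.zeros(shape, dtype=bool), q=0.01, threshold=0.0)

    def test_identical_inputs_empty_mask_empty_list(self):
        freqs = np.arange(1.0, 100.0)
        med = np.ones((3, freqs.size))
        out = differential_peaks(med, med, self.empty_map(freqs, 3), 1, 99)
        assert out.empty

    def test_oculus_peaks_include_52_and_90(self, spectral_results):
        peaks = spectral_results["peaks"]["eyes_closed"]
        found = set(peaks.freq_hz)
        assert any(abs(f - 52.0) <= 0.1 for f in found)
        assert any(abs(f - 90.0) <= 0.1 for f in found)

    def test_vive_profile_no_hmd_band_peaks(self):
        cfg = H.test_preset(seed=21, n_trials_per_task=20,
                            hmd_profile=H.VIVE_LIKE)
        res = spectral_branch(H.simulate_berger_session(cfg, "VR"),
                              H.simulate_berger_session(cfg, "No-VR"))
        for state in ("eyes_closed", "eyes_open"):
            for f in res["peaks"][state].freq_hz:
                assert not (55 < f < 85) and not (95 < f < 120)

    def test_groups_merge_within_two_bins(self):
        freqs = np.arange(0.0, 50.0, 1.0)
        smap = self.empty_map(freqs, 1)
        rej = smap.rejected.copy()
        rej[0, [10, 12, 20]] = True     # 10 & 12 merge; 20 separate
        smap = SignificanceMap(
            channels=smap.channels, freqs=freqs, p=smap.p,
            statistic=smap.statistic, rejected=rej, q=0.01, threshold=1.0)
        vr = np.ones((1, freqs.size))
        vr[0, 12] = 5.0
        vr[0, 20] = 3.0
        out = differential_peaks(vr, np.ones_like(vr), smap, 0, 49)
        assert len(out) == 2
        assert out.freq_hz.tolist() == [12.0, 20.0]
        assert out.ratio.tolist() == [5.0, 3.0]
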