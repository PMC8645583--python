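"""Simulate one eyes-open/eyes-closed session and look at its spectrum.

Builds a reduced-scale (19-channel, 500 Hz) session with an Oculus-like
HMD artifact profile, then prints the strongest spectral lines at Cz.
The 50 Hz mains line and the HMD lines at 52 and 90 Hz (plus harmonics)
should top the list; the 10 Hz entry is the subject's alpha rhythm.
"""

import numpy as np

import hmdeeg as H
from hmdeeg.preprocess import epoch
from hmdeeg.report import preprocess_spectral
from hmdeeg.spectral import median_spectrum, power_spectrum

cfg = H.test_preset(seed=1, n_trials_per_task=20, hmd_profile=H.OCULUS_LIKE)
rec = H.simulate_berger_session(cfg, "VR")
print(f"session: {rec.n_channels} channels, {rec.fs:g} Hz, "
      f"{rec.duration:g} s, {len(rec.events)} eye-state cues")

rec = preprocess_spectral(rec)          # exclusions, 0.1 Hz high-pass, CAR
spec = power_spectrum(epoch(rec, "eyes_closed", 0.0, cfg.trial_s))
med = median_spectrum(spec)[spec.channel_index("Cz")]

# peaks = bins that beat the local spectral median by 5x
print("\nstrongest narrowband components at Cz (median over 20 trials):")
sel = spec.freqs >= 5.0
order = np.argsort(med)[::-1]
shown = []
for i in order:
    f = spec.freqs[i]
    if f < 5.0 or any(abs(f - g) < 1.0 for g in shown):
        continue
    local = np.median(med[max(i - 50, 0):i + 50])
    if med[i] < 5 * local:
        continue
    shown.append(f)
    print(f"  {f:7.1f} Hz   {med[i]:10.3f} µV²")
    if len(shown) >= 8:
        break
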