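# Methods

## What the benchmark measures

An HMD worn over an EEG cap can contaminate the recording in two distinct
ways: narrowband electromagnetic lines in the spectrum, and distortion of
time-locked evoked responses. The benchmark probes both on paired
sessions recorded (or simulated) with and without the device, holding
everything else fixed. A device passes when (i) the only spectral
differences between conditions are explainable artifact lines that the
differential-peak table makes explicit, and (ii) the physiological
measures — the occipital alpha blockade and the N20/P37 somatosensory
components — are unchanged.

## Signal path

Both branches share the conditioning chain: drop the electrodes the HMD
physically displaces plus the mastoids ({Fz, F1, F2, M1, M2}), apply a
0.1 Hz third-order Butterworth high-pass forward and backward (zero net
phase, effective 6th-order magnitude), and re-reference to the common
average. The recording reference (Cz) is kept as an explicit all-zero
channel so the common average is taken over the complete montage; after
CAR the choice of recording reference cancels exactly. The SEP branch
additionally applies a 48–52 Hz zero-phase band-stop, epochs to
[−50, +300) ms around stimulation, and subtracts the per-epoch median
over [−50, −10) ms — the first 40 ms of the pre-stimulus span, kept away
from filtered stimulation-artifact ringing near t = 0. Epoch windows are
half-open `[tmin, tmax)`; boundary trials are dropped and counted, never
zero-padded. No artifact rejection or correction is applied anywhere:
the artifacts are the measurand.

Zero-phase filtering is exact in its passband phase but, like any
forward–backward IIR scheme, leaves edge transients; for the 0.1 Hz
high-pass these decay with a ~3 s time constant, which is why property
tests evaluate the filter away from signal edges.

## Spectral estimation

The per-trial spectrum is deliberately primitive: a rectangular-window
FFT over the full 10 s trial, one-sided scaling P_k = (2/N²)|X_k|² for
interior bins (no doubling at DC/Nyquist), so a sinusoid of amplitude a
on a bin frequency carries a²/2 µV² in exactly one bin and Parseval holds
as Σ_k P_k · N = Σ_n x_n². No tapering, no Welch averaging — narrowband
lines stay maximally concentrated, and robustness comes from taking the
median across trials instead. The relative spectrogram divides each
2.5 s window (step 0.25 s) of every eyes-closed trial by the
across-trial-and-window *median* eyes-open spectrum, then takes the
across-trial median ratio; the median (rather than mean) baseline keeps
a single bad trial from biasing every ratio. The individual alpha peak
is the argmax over 7–14 Hz of the time- and occipital-electrode-averaged
ratio; its ±2 Hz band defines the topography.

## Statistics

The Wilcoxon rank-sum test is implemented directly: midranks for ties;
exact enumeration of all C(n+m, n) rank assignments when n + m ≤ 12
(this doubles as the oracle anchoring the approximation); otherwise a
normal approximation with tie-corrected variance and continuity
correction (verified identical to scipy's asymptotic Mann–Whitney p).
One spectral comparison pools every electrode × bin p-value (bins from
1 Hz to Nyquist) into a single Benjamini–Hochberg family at q = 0.01 —
the conservative reading of "per subject and condition". Differential
peaks group significant bins within 2 bins of each other (absorbing
leakage splatter) and report the bin with the largest electrode-median
VR/No-VR power ratio per group.

A practical floor follows from the discrete null distribution: with n =
m = 10 trials the smallest attainable two-sided approximate p is
~1.8 × 10⁻⁴, which can never pass BH over a pooled family of ~5 × 10⁴
cells at q = 0.01. Detection therefore requires roughly 20 trials per
condition and up; the full design uses 50. The 10-trial preset remains
valid for null calibration, where nothing should be detected.

The SEP comparison runs 8 rank-sum tests (2 electrodes × 2 components ×
{latency, SNR}) as one BH family at q = 0.001. The SNR statistic divides
each epoch's |amplitude| by the interquartile range of the amplitudes
across the condition's epochs ("interquartile" read as qualifying the
dispersion measure, consistent with the otherwise median-based
summaries). Because that denominator is *estimated from the same
epochs*, its sampling error shifts a whole condition's SNR values
coherently; the between-condition SNR rank-sum is therefore somewhat
anti-conservative when the amplitude spread is small relative to its
mean (the spurious standardized shift is O(1) in the epoch count). This
is a property of the statistic itself, not of the implementation, and is
mild at realistic single-trial spreads. Summary dispersion uses the
normal-approximation standard error of a median, 1.2533·sd/√n.

N20/P37 search windows are [15, 25) and [30, 45) ms — conventional
windows around the components' nominal latencies; extrema ties break to
the earliest sample, so an all-zero epoch reports the window start.

## The generator

The generator's defaults are the study conditions; its parts:

* **Background**: spectrally shaped Gaussian noise with one-sided PSD ∝
  1/f^γ above 1 Hz (flat below), γ = 1, normalized analytically so the
  expected RMS equals `background_scale` = 10 µV. γ = 0 yields exactly
  white noise.
* **Alpha**: a sinusoid at `alpha_freq` = 10 Hz (per-subject jitter ±1 Hz
  available) with slow random amplitude modulation, gain 6 µV
  (eyes closed) vs 1 µV (open) at the occipital maximum, spatial profile
  a Gaussian falloff from Oz. An amplitude-switched sinusoid rather than
  filtered noise keeps the peak frequency exact for recovery tests.
* **Mains**: 50 Hz plus 2 harmonics (RMS 5, 2.5, 1.25 µV), one random
  phase per line shared across channels, deterministic per-channel
  coupling weights in [0.5, 1.5] hashed from the electrode label.
  Determinism here is load-bearing: it makes the post-CAR mains power
  identically distributed across independently seeded sessions, so the
  50 Hz bin is a true null for the condition test. Only harmonics that
  clear the 1/f floor are configured — every line the generator injects
  is recoverable from the spectrum, by design.
* **HMD profiles**: "oculus_like" = 52 Hz (+2 harmonics), 90 Hz
  (+2 harmonics), extra lines at 137 and 211 Hz, RMS 1.5–3 µV with
  seeded random per-channel weights and phases (the device affects
  electrodes unevenly); "vive_like" = no lines; "env_87" = an 87 Hz
  environmental line applied to No-VR sessions only. The real devices'
  line amplitudes are not known; these are chosen once for clear
  detectability at the benchmark's scale. Harmonics above Nyquist are
  dropped; a base line at or above Nyquist is an error.
* **SEP**: stimulation trains of 5 sessions × 100 stimulations, ISI
  uniform in [0.2, 0.5] s (2–5 Hz); each stimulus adds Gaussian
  templates — N20: −2 µV, 20 ms latency, 5 ms FWHM; P37: +2.5 µV, 37 ms,
  10 ms — with a topography concentrated midway between C6 and CP4
  (normalized to max 1), plus a 50 µV, 1 ms stimulation-artifact pulse at
  t = 0 with heterogeneous deterministic weights. Successive responses
  overlap (ISI < epoch length) on purpose.

Everything is generated source-side and then re-expressed against Cz
(subtract the Cz row, zero it), mirroring acquisition.

Reduced scale: the `test_preset` uses 19 channels (a 10–20 subset
including Cz, O1/O2, C6/CP4), 500 Hz and 10 trials per task; the full
design is 64 channels at 5,000 Hz with 50 trials. Tests and the
acceptance script run at the reduced scale with 20 trials per task for
detection and 200 × 10-trial replicates for null calibration — sizes
chosen so every statistical claim is measurable with comfortable
margins on a single CPU.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the pipeline
probes: 1/f spectra with narrowband lines, eye-state-switched occipital
alpha, jittered overlapping evoked responses, and exchangeability of
paired null sessions. It does not model volume conduction or realistic
topographies beyond smooth spatial weightings, eye-blink/EMG artifacts,
electrode impedance drift, the anti-aliasing hardware filter, or
steady-state visual responses to display flicker. Passing tests
demonstrate that the pipeline detects what it claims and stays silent
under a true null — not that any particular real HMD is clean.

## Numerical choices

* EDF files use 16-bit samples with per-channel physical ranges set to
  the exact signal range (quantization step = range/65534); non-finite
  or header-unrepresentable values raise rather than clip. Events live
  in a sidecar TSV (`onset_s`, `label`), keeping signal round-trips
  bit-predictable.
* Degenerate inputs fail loudly: zero baseline bins in the relative
  spectrogram, zero IQR in the SNR, all-channel exclusion, aliased
  lines, inverted filter bands, epochs with no surviving trials.
* A flat alpha search range warns and falls back to the range midpoint.
* Seeding: each session derives its stream from (seed, task, condition),
  so a paired session differs between conditions but is byte-identical
  across reruns; report TSVs are byte-stable under a fixed seed.

## Known limitations

* The rank-sum trial-count floor above means small pilot sessions
  (≤ 10 trials/condition) cannot light up the significance map at
  q = 0.01; this is a property of the test, not a bug.
* The SNR statistic's shared-denominator anti-conservativeness (above).
* Differential peaks report the strongest bin per significant group; two
  distinct artifact lines closer than ~3 bins would merge.
* The EDF codec writes plain EDF (events in the TSV sidecar), not EDF+
  embedded annotations, and reads only equal-rate signal sets.
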