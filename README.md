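# tiskit

Modeling tools for **temporal interference stimulation (TIS)** and direct
kHz electrical stimulation of peripheral nerves.

TIS (historically: interferential current stimulation) applies two kHz
sinusoidal carriers at slightly different frequencies, f1 and f2, through
separate electrode pairs. Where the fields interfere, the tissue sees an
amplitude-modulated (AM) kHz field whose beat frequency Δf = f2 − f1 lies in
the physiological range. The method is often described as if neurons
"demodulate" the low-frequency envelope while the carriers themselves are
inert. The biophysics says otherwise: nonlinear Na⁺/K⁺ channel kinetics
rectify a symmetric kHz sine into a net depolarization that sums over
successive cycles (the Gildemeister effect), so the carrier itself drives
excitation and the envelope merely gates *when* threshold is reached. This
package implements the computational side of that argument for researchers
in neurostimulation and bioelectronic medicine:

* **waveforms** — synthesis of the four stimulation conditions (TIS carrier
  pair, additive and multiplicative premodulated AM, gated sine burst,
  unmodulated sine), Hilbert-envelope extraction, modulation index
  (max − min)/(max + min), and band-power spectra (the spectrum of a TIS
  pair contains no energy at Δf).
* **strength_frequency** — the empirical Reilly strength–frequency law for
  sinusoidal thresholds,

      I_TH(f) = I0 · (1 − e^(−500/f))^(−0.9) · (1 − e^(−f/10))^(−0.8),

  evaluated and least-squares fitted on log-thresholds with the scale
  factor I0 free.
* **axon_model** — a surrogate myelinated axon (active Hodgkin–Huxley-type
  nodes with a slow accommodation current, resistive internodes, point-source
  extracellular drive) demonstrating kHz rectification, temporal summation,
  beat-locked burst firing, and threshold-versus-frequency behaviour, with
  staircase-style threshold bisection.
* **tot_analysis** — the closed-form **time over threshold** statistic: the
  fraction of each beat period that the combined activating function of two
  carriers with amplitudes A1, A2 exceeds a common threshold A_T,

      TOT = 0                                  if A1 + A2 < A_T
      TOT = arccos((A_T² − A1² − A2²)/(2 A1 A2)) / π    otherwise
      TOT = 1                                  if |A1 − A2| > A_T,

  classifying tissue as subthreshold, phasic (0 < TOT < 1) or tonic.
* **volume_conductor** — a frequency-domain finite-volume solver for a
  layered skin/fat/muscle forearm block with anisotropic muscle, a
  constant-phase-element electrode–skin interface
  (Y = 1/R_p + (jω)^α/K), per-pair superposition, activating-function maps
  A = |d²V/dx²| on the nerve plane, TOT maps under current steering, and a
  2-D disc comparison showing that 4-electrode TIS is *bimodal* (tonic
  shells around the electrodes plus a phasic hotspot) while 2-electrode
  premodulated AM is *monomodal*.
* **synthetic_data / analysis_pipeline** — a generator for per-subject
  threshold studies (Reilly frequency dependence, lognormal subject and
  residual effects, waveform ratio multipliers, staircase ramp
  quantization, AMF U-curves) and the standard summaries: pooled Reilly
  fits, threshold-ratio means ± SEM, and per-subject i/i_min normalization.

## Worked example

Generate a synthetic locust-style threshold study (5 subjects, 8 carrier
frequencies from 0.5 to 12.5 kHz, three waveforms), fit the Reilly law per
waveform and summarize the threshold ratios:

```bash
tis-kit run-study --model locust --subjects 5 --seed 3 --out report.json
```

```
Study report
============
    sine: I0 = 0.03974 mA, R^2 = 0.9979
      am: I0 = 0.05077 mA, R^2 = 0.9990
   burst: I0 = 0.04262 mA, R^2 = 0.9984
  am/sine: 1.280 +/- 0.013 (n = 40)
  burst/sine: 1.075 +/- 0.013 (n = 40)
```

All three waveforms follow the same U-shaped strength–frequency law
(R² ≥ 0.998 here); the AM-to-sine threshold ratio recovered from the noisy,
staircase-quantized data (1.280) sits close to the generator's configured
locust effect (1.29) — the signature that amplitude modulation shifts
thresholds only by a modest multiplicative factor while the carrier
frequency dominates.

The time-over-threshold statistic classifies a tissue location directly:

```bash
tis-kit tot --a1 2.0 --a2 0.5 --at 1.0
# {"tot": 1.0, "region": "tonic"}
```

Here the unmodulated floor |A1 − A2| = 1.5 exceeds A_T, so the location is
driven tonically — it never drops below threshold during the beat.

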