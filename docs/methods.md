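# Methods

This note documents the models behind `tiskit`, the defaults they use, the
numerical choices, and what the synthetic data do and do not capture.

## Waveforms and envelopes

Four stimulation conditions are built from kHz carriers: a TIS pair (two
tones at f1 and f2 = f1 + Δf on separate channels), additive premodulated
AM (their sum on one channel), multiplicative AM
(2A·cos(πΔf·t)·sin(2π(f1 + Δf/2)·t), identical to the additive form by the
product-to-sum identity, and generated at full modulation depth to match
it), a sine burst (carrier gated on/off at the modulation frequency, duty
0.5 by default), and an unmodulated sine. The reported "carrier frequency"
is always f1. Default sampling is 100 samples per carrier period with a
hard floor of 40; below the floor synthesis is refused rather than silently
aliased.

Envelopes are the magnitude of the analytic (Hilbert) signal smoothed by a
moving average over one carrier period. For a two-tone sum the analytic
magnitude equals the beat envelope sqrt(A1² + A2² + 2A1A2·cos(2πΔf·t))
exactly, and the smoothing only rounds the cusp at envelope zeros, so the
approach works for both beats and gated bursts. The modulation index
(max − min)/(max + min) is taken over whole modulation periods when the
modulation frequency is supplied, otherwise over the central 80 % of the
record, to avoid filter edge bias. Band power integrates a Hann-windowed
one-sided periodogram over the requested band.

## Strength–frequency law

Sinusoidal threshold currents follow the empirical Reilly form

    I_TH(f) = I0 (1 − e^(−500 Hz/f))^(−0.9) (1 − e^(−f/10 Hz))^(−0.8),

a U-shaped curve rising below ~40 Hz (accommodation) and above ~1 kHz.
Fitting is least squares on log-thresholds — thresholds span more than a
decade over 0.5–12.5 kHz and their errors are multiplicative — with only
I0 free by default (closed-form solution); an opt-in flag frees all five
parameters via Levenberg–Marquardt. R² is reported on log-thresholds as
1 − SSE/SST.

## Surrogate axon

The axon is a chain of 51 active nodes, 1 mm apart, joined by purely
resistive internodes (myelin treated as a perfect insulator; internodal
membrane omitted). Each node carries classic squid-type Na⁺/K⁺/leak
kinetics with three adjustments, chosen once when the model was designed:

* a temperature factor of 3 on the m/h/n rates, giving kHz-capable sodium
  activation;
* a +4 mV depolarizing shift of the slow gates h and n. Unmodified squid
  kinetics accommodate so strongly that a slowly rising beat envelope needs
  ~6× more current than an abrupt sine onset, contradicting the
  near-equality of modulated and unmodulated kHz thresholds seen in
  peripheral nerve; the shift weakens subthreshold inactivation and brings
  the ratio to ≈1.1–1.3;
* a slow potassium accommodation current (0.2 mS/cm², activation midpoint
  −50 mV, τ = 150 ms) that penalises very slowly rising envelopes, the
  mechanism behind the rising low-AMF branch of the threshold-versus-beat-
  frequency U-curve.

Node geometry: 10 µm diameter, 1.5 µm nodal length, 2 µF/cm², axoplasm
70 Ω·cm. The extracellular drive is a monopolar point source 1 mm from the
central node in a 300 Ω·cm medium, Ve = ρI/(4πr); for two-carrier
conditions the channel currents are summed into this single source, which
makes TIS and additive AM identical at the fibre — the appropriate
idealisation for a model probing the waveform, not the montage. Modulated
drives are phased sin(2πf1t) − sin(2πf2t) so the beat envelope starts at
zero: an envelope-maximum cold start would probe the fully rested membrane
on the first beat only and report a threshold that later beats cannot
reproduce.

Integration is semi-implicit and unconditionally stable: Rush–Larsen
exponential gate updates followed by a backward-Euler tridiagonal solve for
the membrane potentials. The default step is min(25 µs, 1/(100·f)) with a
hard floor of 1/(40·f). Traces are recorded at 50 µs. A run aborts as a
numerical blow-up when any node further than 4 internodes from the source
exceeds |Vm| = 200 mV or any value becomes non-finite; the few nodes
nearest the source are exempt because the stimulus artifact there scales
with the drive and legitimately passes 200 mV at strong amplitudes.

Spikes are upward 0 mV crossings merged within 1 ms. A stimulus counts as
suprathreshold when a spike appears at least 5 internodes from the node
nearest the source (propagation, excluding local depolarisation).
Thresholds are found by geometric bisection to 1 % relative tolerance over
a fixed window of max(2 s, 2 modulation periods); by default the bracket is
grown by doubling from 20 µA until a spike appears, mimicking the
experimental staircase and keeping probe amplitudes near threshold.

What the surrogate shows, at its own current scale (no claim is made about
absolute milliampere values of any anatomical fibre): net depolarization
under subthreshold kHz drive that vanishes when the channels are frozen;
repetitive firing above threshold; one spike burst per beat under
two-carrier drive (inter-burst interval = 1/Δf); thresholds monotone in
carrier frequency over 1–10 kHz; and a U-shaped dependence on beat
frequency. Its U-curve optimum sits near 50 Hz — the surrogate's preferred
firing rate — which is higher than the ~5 Hz optimum of human motor
fibres, so beat-frequency tests use a grid (1, 50, 400 Hz at a 3 kHz
carrier) that brackets the surrogate's own optimum.

## Time over threshold

At a point where the two carriers produce activating-function amplitudes
A1 and A2, the beat envelope is sqrt(A1² + A2² + 2A1A2 cos(2πΔf t)) and
the fraction of each beat period at or above a threshold A_T has the
closed form given in the README. The arccos argument is clamped to [−1, 1]
so the branches meet continuously; envelope values exactly at threshold
count as "over", and results within 1e−12 of 0 or 1 snap to the
subthreshold/tonic labels. A dense-sampling oracle (fraction of ≥ A_T
samples over one beat, 10⁴ samples by default) provides an independent
check; it agrees with the closed form to the sampling resolution and is
invariant to Δf, which only rescales time.

One structural fact worth noting: TOT is *not* monotone in each amplitude
separately. Adding a weak second carrier to a dominant, just-suprathreshold
one introduces envelope dips below A_T and lowers TOT (for a2² > a1² + A_T²
the derivative with respect to a1 is negative). TOT is monotone
non-increasing in A_T, non-decreasing under joint scaling of both
amplitudes, and non-decreasing in the dominant amplitude.

## Volume conductor

The forearm is a rectangular block of skin (1.5 mm), fat (5 mm) and muscle
(remainder), with the nerve running along x at 10 mm depth. Conductivities
and relative permittivities at 2.5 kHz: muscle 0.6 S/m and 1.5·10⁵ along
the fibres, 0.35 S/m and 1·10⁵ across; fat 0.024 S/m and 3000; skin
0.0015 S/m and 40000; gel 0.27 S/m. Layer thicknesses are configurable
defaults. The complex continuity equation ∇·((σ + jωε₀εr)∇V) = 0 is
discretised by a cell-centred finite-volume scheme on a tensor-product
grid — uniform 4 mm laterally by default, graded in depth, with optional
explicit edge overrides for locally refined oracle comparisons — using
series (harmonic) face conductances across layer interfaces, and solved
with a sparse direct factorisation (real-valued when no permittivity is
present). One cell is pinned to fix the potential gauge of the pure
Neumann problem.

Each gel electrode is a floating equipotential unknown coupled to the skin
cells beneath it through the electrode–skin interface admittance per area
Y = 1/R_p + (jω)^α/K with K = 35 MΩ·s^−α·cm², α = 0.9 and
R_p = 4.7 MΩ·cm² (converted to S/m²), in series with the half-cell bulk
path. Active electrodes carry a prescribed total current (an exact
constraint row, so conservation holds to solver precision); inactive
electrodes float at zero net current. The two carrier pairs are solved
independently and superposed, matching isolated current sources, and both
are solved at the single frequency f1 since Δf ≪ f1 leaves the transfer
functions indistinguishable.

Activating functions A = |d²V/dx²| are central second differences (with
the non-uniform-spacing generalisation) of the complex potential on the
nerve plane. A1 vanishes identically at the montage midpoint of an
antisymmetric pair — the activating function of each pair has lobes, not a
central peak — so point probes in convergence tests sit off that cusp or
average over a window. TOT maps apply the closed form element-wise with
A_T = 1000 V/m² by default, the activation threshold associated with a
2.5 kHz carrier; A_T is an input calibration, not a computed quantity,
because it depends on electrode geometry details that are not part of this
model. The qualitative regimes are reproduced with a crossed four-electrode
montage straddling the nerve: equal pair currents make the nerve midpoint
phasic while shells near the electrodes are tonic (bimodal stimulation),
and steering the same total current 1:9 between the pairs drives the nerve
tonically.

The 2-D disc model compares TIS (two diametral point-injection pairs at
45°/225° and 135°/315°) with premodulated AM through one of those pairs at
twice the per-channel amplitude. It solves the Laplace equation on a polar
finite-volume grid (60 × 240 cells by default) and reports the scaled
field Ē = E·σ·d/I, which depends only on geometry. Envelope extremes at a
point are |E1 ± E2| of the two carrier field vectors; the centre value
averages the innermost ring so odd components cancel. An analytic check is
available: for a source/sink pair on the rim of an insulated disc the
potential is −(1/πσt)·ln(|z − a|/|z − b|).

Field exports are legacy ASCII VTK structured grids plus CSV slices.

## Synthetic threshold studies

The generator emulates three preparations — locust leg nerve, human median
nerve motor and sensory — with the model

    I(subject, waveform, f) = I0 · Reilly(f) · m_waveform · e^b_s · e^ε,

lognormal subject effects b_s ~ N(0, 0.2²) and residuals ε ~ N(0, 0.05²),
and a ceiling quantization to the staircase grid: 5/50 µA steps below/at
5 kHz for the locust, 25/250 µA for humans (the experimental ramp's
descend-and-re-ascend bracketing nets out to grid snapping). Waveform
multipliers relative to the unmodulated sine default to the preparation's
observed effects — locust AM 1.29, burst 1.06; human motor 0.99/0.97;
human sensory 0.93/0.84 — with TIS generated as AM (same modulated field;
currents reported per carrier, of which TIS injects two). Base scales I0
(locust 0.04 mA, human motor 1.0 mA, human sensory 0.5 mA) put thresholds
in each preparation's working range. The default carrier grid is the
8-point set {0.5, 1, 2.5, 5, 7.5, 10, 11.5, 12.5} kHz.

Beat-frequency (AMF) designs use a fixed 3 kHz carrier and a log-normal
dip: threshold(AMF) = plateau·(1 − 0.2·exp(−ln²(AMF/AMF_opt)/(2·1.5²))),
with the optimum at 5 Hz (motor) or 1 Hz (sensory) and a 20 % depth.

The generator reproduces the *statistical structure* of such studies —
multiplicative noise, subject heterogeneity, staircase quantization,
ratio effects, U-curves. It does not model perception or report bias (the
burst waveform's sensory-contrast advantage enters only through its net
multiplier), electrode placement variability, or any within-session drift;
passing tests therefore validate the estimators under the stated noise
model, not those real-world effects.

## Analysis pipeline

Reilly fits pool each waveform's thresholds to per-frequency geometric
means before fitting (subject effects are multiplicative, so the geometric
mean is the natural pooled estimate). Threshold ratios are formed on
matched (subject, frequency) pairs and averaged with their SEM over the
pooled pairs; a per-frequency pooling mode is provided since the original
summaries are ambiguous about the order. AMF curves are normalized
per subject by that subject's minimum (i/i_min) and then averaged per AMF;
because subjects place their minima at different AMFs the averaged curve
exceeds 1 everywhere. Inferential statistics (mixed models, post-hoc
tests) are deliberately out of scope; the CSV outputs feed any external
statistics tool.

Parameter-recovery checks isolate the measurement-noise contribution
(subject SD set to 0 and the staircase disabled) because with N = 8
subjects the subject random effect alone leaves a ±7 % uncertainty on the
recovered I0 and the staircase ceiling adds a systematic +3–4 %: with the
full noise model I0 is simply not identifiable to 5 % at that sample size.
Ratio checks keep the full noise model, since subject effects cancel in
matched ratios.

## Problem sizes and runtimes

Defaults are desk-scale by design: axon simulations integrate 51 nodes at
10–25 µs steps over 2 s windows (seconds per run, with the kernel JIT
compiled); forearm solves use ~30 000–50 000 cells (tens of seconds);
oracle and convergence grids refine locally rather than globally. The
acceptance script completes in well under a minute.

## Known limitations

* The axon is a phenomenological surrogate: absolute thresholds, conduction
  block at high kHz amplitudes, and the 5 Hz beat-frequency optimum of
  human motor fibres are outside its scope.
* The volume conductor is a flat layered block with square patch
  electrodes; curved anatomy, tissue dispersion away from 2.5 kHz, and
  Joule heating are not modeled.
* The scalar TOT ignores the relative phase of the two carriers (the 180°
  phase shift between hotspots perpendicular to the electrode axes).
* The stimulator hardware's current roll-off with frequency is not
  modeled; synthesized amplitudes are the amplitudes the tissue receives.
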