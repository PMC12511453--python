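"""Synthesis and envelope analysis of kHz stimulation waveforms.

Four stimulation conditions built from kHz sine carriers are supported:

* ``tis_pair`` — two unmodulated carriers at f1 and f2 = f1 + delta_f on two
  separate channels; their interference in tissue produces the amplitude
  modulation (temporal interference stimulation, TIS).
* ``am_additive`` — the arithmetic sum of the two carriers on one channel
  (premodulated AM, mimicking the modulation TIS creates in tissue).
* ``am_multiplicative`` — 2A cos(pi df t) sin(2 pi fc t) with
  fc = f1 + df/2, identical to the additive form by the product-to-sum
  identity.
* ``sine_burst`` — a single carrier gated on/off at the modulation frequency.
* ``sine`` — an unmodulated carrier.

Envelope extraction uses the analytic-signal (Hilbert) magnitude smoothed
over one carrier period, which is robust both for two-tone beats and for
gated bursts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import hilbert, get_window

__all__ = [
    "CarrierTone",
    "WaveformSpec",
    "SampledSignal",
    "synthesize",
    "envelope",
    "modulation_index",
    "band_power",
    "DEFAULT_SAMPLES_PER_PERIOD",
    "MIN_SAMPLES_PER_PERIOD",
]

WAVEFORM_KINDS = ("tis_pair", "am_additive", "am_multiplicative", "sine_burst", "sine")

#: Default sampling density, in samples per carrier period.
DEFAULT_SAMPLES_PER_PERIOD = 100
#: Hard floor on sampling density; below this synthesis is rejected.
MIN_SAMPLES_PER_PERIOD = 40


@dataclass(frozen=True)
class CarrierTone:
    """A single sinusoidal carrier: ``amplitude * sin(2 pi f t + phase)``."""

    frequency: float  # Hz
    amplitude: float  # mA
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("carrier frequency must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("carrier amplitude must be non-negative")


@dataclass(frozen=True)
class WaveformSpec:
    """Specification of one stimulation condition.

    ``carrier_frequency`` is f1; for the two-carrier kinds the second carrier
    sits at f2 = f1 + ``modulation_frequency``.  ``modulation_frequency`` is
    the beat / amplitude-modulation frequency (AMF); 0 means unmodulated.
    ``per_channel_amplitude`` is the amplitude of each carrier (mA).
    """

    kind: str
    carrier_frequency: float  # Hz (f1)
    modulation_frequency: float = 0.0  # Hz (delta f / AMF)
    per_channel_amplitude: float = 1.0  # mA
    duration: float = 1.0  # s
    burst_duty: float = 0.5  # fraction of each AMF period the burst is on

    def __post_init__(self) -> None:
        if self.kind not in WAVEFORM_KINDS:
            raise ValueError(f"kind must be one of {WAVEFORM_KINDS}, got {self.kind!r}")
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be strictly positive")
        if self.modulation_frequency < 0:
            raise ValueError("modulation_frequency must be non-negative")
        if self.modulation_frequency >= self.carrier_frequency / 2:
            raise ValueError(
                "modulation_frequency must be below carrier_frequency / 2"
            )
        if self.kind == "sine" and self.modulation_frequency != 0:
            raise ValueError("an unmodulated sine must have modulation_frequency = 0")
        if self.per_channel_amplitude < 0:
            raise ValueError("per_channel_amplitude must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be strictly positive")
        if not (0 < self.burst_duty <= 1):
            raise ValueError("burst_duty must lie in (0, 1]")

    @property
    def f2(self) -> float:
        """Frequency of the second carrier, f1 + delta_f."""
        return self.carrier_frequency + self.modulation_frequency

    @property
    def highest_frequency(self) -> float:
        # the multiplicative form has sidebands at f1 and f1 + df too
        if self.kind in ("tis_pair", "am_additive", "am_multiplicative"):
            return self.f2
        return self.carrier_frequency

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WaveformSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform (or envelope) with its sample rate."""

    sample_rate: float  # Hz
    samples: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_csv(self, path) -> None:
        """Write as two-column CSV ``time_s,value_mA``."""
        data = np.column_stack([self.times, self.samples])
        np.savetxt(path, data, delimiter=",", header="time_s,value_mA", comments="")


def _time_axis(spec: WaveformSpec, sample_rate: float) -> np.ndarray:
    n = int(round(spec.duration * sample_rate))
    return np.arange(n) / sample_rate


def default_sample_rate(spec: WaveformSpec) -> float:
    return DEFAULT_SAMPLES_PER_PERIOD * spec.highest_frequency


def synthesize(
    spec: WaveformSpec, sample_rate: float | None = None
) -> list[SampledSignal]:
    """Synthesize a stimulation condition.

    Returns two channels for ``tis_pair`` (one per carrier) and a single
    channel otherwise.
    """
    if sample_rate is None:
        sample_rate = default_sample_rate(spec)
    required = MIN_SAMPLES_PER_PERIOD * spec.highest_frequency
    if sample_rate < required:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz is below the "
            f"{MIN_SAMPLES_PER_PERIOD}-samples-per-period floor; "
            f"need at least {required:g} Hz"
        )
    t = _time_axis(spec, sample_rate)
    a = spec.per_channel_amplitude
    f1 = spec.carrier_frequency
    df = spec.modulation_frequency

    if spec.kind == "tis_pair":
        s1 = a * np.sin(2 * np.pi * f1 * t)
        s2 = a * np.sin(2 * np.pi * spec.f2 * t)
        return [
            SampledSignal(sample_rate, s1, "carrier_1"),
            SampledSignal(sample_rate, s2, "carrier_2"),
        ]
    if spec.kind == "am_additive":
        s = a * np.sin(2 * np.pi * f1 * t) + a * np.sin(2 * np.pi * spec.f2 * t)
        return [SampledSignal(sample_rate, s, "am_additive")]
    if spec.kind == "am_multiplicative":
        fc = f1 + df / 2.0
        s = 2 * a * np.cos(np.pi * df * t) * np.sin(2 * np.pi * fc * t)
        return [SampledSignal(sample_rate, s, "am_multiplicative")]
    if spec.kind == "sine_burst":
        s = a * np.sin(2 * np.pi * f1 * t)
        if df > 0:
            phase = (t * df) % 1.0
            s = np.where(phase < spec.burst_duty, s, 0.0)
        return [SampledSignal(sample_rate, s, "sine_burst")]
    # unmodulated sine
    s = a * np.sin(2 * np.pi * f1 * t)
    return [SampledSignal(sample_rate, s, "sine")]


def envelope(signal: SampledSignal, carrier_frequency: float) -> SampledSignal:
    """Slowly varying amplitude of a carrier-borne signal.

    Analytic-signal magnitude followed by a moving average over one carrier
    period.  For a sum of two tones with amplitudes A1, A2 offset by delta_f
    this converges to sqrt(A1^2 + A2^2 + 2 A1 A2 cos(2 pi delta_f t)) away
    from the record edges.
    """
    if carrier_frequency <= 0:
        raise ValueError("carrier_frequency must be strictly positive")
    n_per_period = signal.sample_rate / carrier_frequency
    if n_per_period < 4:
        raise ValueError(
            f"carrier at {carrier_frequency:g} Hz is not resolvable at "
            f"sample rate {signal.sample_rate:g} Hz"
        )
    if len(signal.samples) < 10 * n_per_period:
        raise ValueError("signal must contain at least 10 carrier periods")
    mag = np.abs(hilbert(signal.samples))
    win = max(2, int(round(n_per_period)))
    kernel = np.ones(win) / win
    smooth = np.convolve(mag, kernel, mode="same")
    return SampledSignal(signal.sample_rate, smooth, f"envelope({signal.channel_label})")


def modulation_index(
    env: SampledSignal, modulation_frequency: float | None = None
) -> float:
    """Modulation depth (max - min) / (max + min) of an envelope.

    If ``modulation_frequency`` is given, extrema are taken over the largest
    whole number of modulation periods (edge-trimmed by one carrier-scale
    margin is unnecessary then); otherwise the central 80 % of the record is
    used to avoid filter edge bias.
    """
    x = env.samples
    if np.any(x < 0):
        raise ValueError("envelope must be non-negative")
    if not np.any(x > 0):
        raise ValueError("modulation index undefined for an all-zero envelope")
    n = len(x)
    if modulation_frequency is not None and modulation_frequency > 0:
        per = env.sample_rate / modulation_frequency
        k = int(n // per)
        if k < 1:
            raise ValueError("envelope shorter than one modulation period")
        # drop half a period at each edge when we can afford it
        if k >= 2:
            start = int(per // 2)
            x = x[start : start + int((k - 1) * per)]
        else:
            x = x[: int(k * per)]
    else:
        lo, hi = int(0.1 * n), int(0.9 * n)
        x = x[lo:hi]
    top, bot = float(np.max(x)), float(np.min(x))
    if top + bot == 0:
        raise ValueError("modulation index undefined for an all-zero envelope")
    return (top - bot) / (top + bot)


def band_power(signal: SampledSignal, center: float, halfwidth: float) -> float:
    """Integrated spectral power in [center - halfwidth, center + halfwidth].

    A Hann window suppresses leakage from strong out-of-band carriers.
    Power is reported in signal units squared (one-sided density integrated
    over the band).
    """
    fs = signal.sample_rate
    if center + halfwidth >= fs / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    x = signal.samples
    n = len(x)
    win = get_window("hann", n)
    xw = (x - 0.0) * win
    spec = np.fft.rfft(xw)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # one-sided power spectrum normalised so that a full-band sum gives the
    # windowed mean-square value
    psd = (np.abs(spec) ** 2) / (np.sum(win**2) * fs)
    psd[1:] *= 2.0
    mask = (freqs >= center - halfwidth) & (freqs <= center + halfwidth)
    df = fs / n
    return float(np.sum(psd[mask]) * df)
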