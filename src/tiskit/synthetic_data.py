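"""Synthetic threshold-study generator.

Emulates the statistical structure of per-subject nerve-stimulation
threshold studies on three preparations:

* ``locust`` — insect leg-nerve (N5) stimulation, thresholds well below
  1 mA at low kHz carriers;
* ``human_motor`` — median-nerve motor branch in the forearm;
* ``human_sensory`` — median-nerve sensory fibres at the wrist.

The generative model for a strength-frequency (s-f) design is

    I(subject, waveform, f) = I0 * Reilly(f) * m_waveform
                              * exp(b_subject) * exp(eps)

with lognormal subject effects ``b_subject ~ N(0, sd_subject^2)`` and
residuals ``eps ~ N(0, sd_residual^2)``, followed by ramp quantization:
the experimental staircase raises the current in fixed steps, so a measured
threshold is the smallest step-grid multiple at or above the true one.

Waveform multipliers default to the ratios each preparation exhibits
relative to the unmodulated sine (AM/sine and burst/sine); TIS is generated
as the AM waveform (same modulated field; per-carrier current reported).

AMF (beat-frequency) designs follow a shallow U-curve in log-AMF:

    I(AMF) = plateau * (1 - depth * exp(-(ln(AMF/AMF_opt))^2 / (2 w^2)))

with an optimum around 5 Hz (motor) or 1 Hz (sensory) and a ~20 % dip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strength_frequency import ReillyParams, reilly_threshold, THRESHOLD_COLUMNS

__all__ = [
    "SyntheticStudyConfig",
    "generate_sf_dataset",
    "generate_amf_dataset",
    "apply_ramp_quantization",
    "dataset_to_csv",
    "DEFAULT_FREQUENCY_GRID",
    "MODEL_DEFAULTS",
]

#: 8-point carrier-frequency grid (Hz) spanning the 0.5-12.5 kHz design.
DEFAULT_FREQUENCY_GRID = (500.0, 1000.0, 2500.0, 5000.0, 7500.0, 10000.0, 11500.0, 12500.0)

#: Per-preparation defaults: waveform threshold multipliers relative to the
#: unmodulated sine, base scale I0 (mA), staircase steps (mA) below/at-or-
#: above 5 kHz, and the AMF U-curve optimum (Hz).
MODEL_DEFAULTS = {
    "locust": dict(
        multipliers={"sine": 1.0, "am": 1.29, "burst": 1.06, "tis": 1.29},
        base_i0=0.04,
        ramp_step_low=0.005,
        ramp_step_high=0.05,
        amf_optimum=5.0,
    ),
    "human_motor": dict(
        multipliers={"sine": 1.0, "am": 0.99, "burst": 0.97, "tis": 0.99},
        base_i0=1.0,
        ramp_step_low=0.025,
        ramp_step_high=0.25,
        amf_optimum=5.0,
    ),
    "human_sensory": dict(
        multipliers={"sine": 1.0, "am": 0.93, "burst": 0.84, "tis": 0.93},
        base_i0=0.5,
        ramp_step_low=0.025,
        ramp_step_high=0.25,
        amf_optimum=1.0,
    ),
}

#: Carrier frequency at which steps switch from the fine to the coarse grid.
RAMP_STEP_SWITCH_HZ = 5000.0


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Design and noise parameters of one synthetic threshold study."""

    model: str = "locust"
    n_subjects: int = 5
    carrier_frequencies: tuple = DEFAULT_FREQUENCY_GRID
    waveforms: tuple = ("sine", "am", "burst")
    multipliers: dict | None = None  # waveform -> threshold ratio vs sine
    subject_sd: float = 0.2  # lognormal subject effect SD (log scale)
    residual_sd: float = 0.05  # lognormal residual SD (log scale)
    base_i0: float | None = None  # mA; per-model default if None
    ramp_step_low: float | None = None  # mA, carriers < 5 kHz
    ramp_step_high: float | None = None  # mA, carriers >= 5 kHz
    amf_optimum: float | None = None  # Hz
    amf_dip_depth: float = 0.2  # fractional threshold drop at the optimum
    amf_log_width: float = 1.5  # U-curve width in ln(AMF) units
    amf_carrier: float = 3000.0  # Hz, fixed carrier for AMF designs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_DEFAULTS:
            raise ValueError(f"model must be one of {sorted(MODEL_DEFAULTS)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0 <= self.amf_dip_depth < 1):
            raise ValueError("amf_dip_depth must lie in [0, 1)")
        if self.amf_log_width <= 0:
            raise ValueError("amf_log_width must be positive")
        for m in (self.multipliers or {}).values():
            if m <= 0:
                raise ValueError("waveform multipliers must be positive")
        for name in ("base_i0", "ramp_step_low", "ramp_step_high"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    # resolved (per-model default aware) accessors -------------------------
    def _default(self, key: str):
        return MODEL_DEFAULTS[self.model][key]

    @property
    def resolved_multipliers(self) -> dict:
        return dict(self.multipliers or self._default("multipliers"))

    @property
    def resolved_i0(self) -> float:
        return self.base_i0 if self.base_i0 is not None else self._default("base_i0")

    @property
    def resolved_amf_optimum(self) -> float:
        return (
            self.amf_optimum
            if self.amf_optimum is not None
            else self._default("amf_optimum")
        )

    def ramp_step(self, carrier_hz: float) -> float:
        lo = (
            self.ramp_step_low
            if self.ramp_step_low is not None
            else self._default("ramp_step_low")
        )
        hi = (
            self.ramp_step_high
            if self.ramp_step_high is not None
            else self._default("ramp_step_high")
        )
        return hi if carrier_hz >= RAMP_STEP_SWITCH_HZ else lo


def apply_ramp_quantization(true_threshold, step: float):
    """Smallest integer multiple of ``step`` that is >= the true threshold.

    Models the experimental staircase: current rises in fixed increments, so
    the recorded threshold snaps up to the step grid.  ``step = 0`` disables
    quantization.  Accepts scalars or arrays.
    """
    x = np.asarray(true_threshold, dtype=float)
    if np.any(x <= 0):
        raise ValueError("true threshold must be strictly positive")
    if step < 0:
        raise ValueError("step must be non-negative")
    if step == 0:
        return float(x) if np.isscalar(true_threshold) else x
    # guard against ceil(k) -> k+1 when x is an exact multiple up to fp error
    q = np.ceil(np.round(x / step, 9)) * step
    return float(q) if np.isscalar(true_threshold) else q


def _subject_effects(cfg: SyntheticStudyConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)


def generate_sf_dataset(cfg: SyntheticStudyConfig) -> pd.DataFrame:
    """Per-subject strength-frequency threshold table (ramp-quantized)."""
    rng = np.random.default_rng(cfg.seed)
    mult = cfg.resolved_multipliers
    params = ReillyParams(i0=cfg.resolved_i0)
    b = _subject_effects(cfg, rng)
    rows = []
    for s in range(cfg.n_subjects):
        for w in cfg.waveforms:
            if w not in mult:
                raise ValueError(f"no multiplier configured for waveform {w!r}")
            for f in cfg.carrier_frequencies:
                eps = rng.normal(0.0, cfg.residual_sd)
                true = reilly_threshold(f, params) * mult[w] * np.exp(b[s] + eps)
                meas = apply_ramp_quantization(true, cfg.ramp_step(f))
                rows.append((f"S{s + 1:02d}", w, f, 0.0, meas))
    return pd.DataFrame(rows, columns=list(THRESHOLD_COLUMNS))


def generate_amf_dataset(cfg: SyntheticStudyConfig, amf_grid) -> pd.DataFrame:
    """Per-subject thresholds versus beat frequency (U-curve design).

    The ``amf_hz`` column holds the modulation frequency; the carrier is
    fixed at ``cfg.amf_carrier``.
    """
    amf_grid = np.asarray(amf_grid, dtype=float)
    if np.any(amf_grid <= 0):
        raise ValueError("amf grid must be strictly positive")
    rng = np.random.default_rng(cfg.seed)
    plateau = reilly_threshold(cfg.amf_carrier, ReillyParams(i0=cfg.resolved_i0))
    opt = cfg.resolved_amf_optimum
    b = _subject_effects(cfg, rng)
    step = cfg.ramp_step(cfg.amf_carrier)
    rows = []
    for s in range(cfg.n_subjects):
        for amf in amf_grid:
            dip = cfg.amf_dip_depth * np.exp(
                -(np.log(amf / opt) ** 2) / (2.0 * cfg.amf_log_width**2)
            )
            eps = rng.normal(0.0, cfg.residual_sd)
            true = plateau * (1.0 - dip) * np.exp(b[s] + eps)
            meas = apply_ramp_quantization(true, step)
            rows.append((f"S{s + 1:02d}", "am", cfg.amf_carrier, amf, meas))
    return pd.DataFrame(rows, columns=list(THRESHOLD_COLUMNS))


def dataset_to_csv(data: pd.DataFrame, path=None) -> str | None:
    """Write (or return) the canonical CSV form of a threshold table."""
    if path is None:
        buf = io.StringIO()
        data.to_csv(buf, index=False)
        return buf.getvalue()
    data.to_csv(path, index=False)
    return None
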