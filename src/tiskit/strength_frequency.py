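"""Strength-frequency (s-f) threshold curves for sinusoidal stimulation.

The threshold current of sinusoidal nerve stimulation versus frequency is
U-shaped: it rises at very low frequencies (accommodation) and at high, kHz
frequencies.  The empirical form used here is the Reilly equation

    I_TH(f) = I0 * (1 - exp(-500/f))**(-0.9) * (1 - exp(-f/10))**(-0.8)

with a single free scale factor ``I0`` (mA); the four shape constants
(500 Hz, exponent 0.9; 10 Hz, exponent 0.8) are fixed unless explicitly
unlocked.  Fitting is performed on log-thresholds because measured
thresholds span more than a decade across 0.5-12.5 kHz and their errors are
multiplicative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ReillyParams",
    "reilly_threshold",
    "fit_reilly",
    "load_threshold_table",
    "validate_threshold_table",
    "THRESHOLD_COLUMNS",
]

#: Canonical CSV schema for per-subject threshold records.
THRESHOLD_COLUMNS = ("subject", "waveform", "carrier_hz", "amf_hz", "threshold_ma")


@dataclass(frozen=True)
class ReillyParams:
    """Parameters of the Reilly s-f equation (shape constants fixed)."""

    i0: float  # mA, overall scale
    high_freq_constant: float = 500.0  # Hz
    high_freq_exponent: float = 0.9
    accommodation_constant: float = 10.0  # Hz
    accommodation_exponent: float = 0.8

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be strictly positive")
        if self.high_freq_constant <= 0 or self.accommodation_constant <= 0:
            raise ValueError("frequency constants must be strictly positive")


def reilly_threshold(frequency, params: ReillyParams):
    """Threshold current I_TH(f) in mA; accepts scalars or arrays."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    hf = (1.0 - np.exp(-params.high_freq_constant / f)) ** (-params.high_freq_exponent)
    lf = (1.0 - np.exp(-f / params.accommodation_constant)) ** (
        -params.accommodation_exponent
    )
    out = params.i0 * hf * lf
    return float(out) if np.isscalar(frequency) else out


def _log_shape(f: np.ndarray, params: ReillyParams) -> np.ndarray:
    """log of the frequency-dependent factor (i0 = 1)."""
    return np.log(reilly_threshold(f, replace(params, i0=1.0)))


def fit_reilly(
    data: pd.DataFrame,
    free_shape: bool = False,
) -> tuple[ReillyParams, float]:
    """Least-squares Reilly fit on log-thresholds.

    Parameters
    ----------
    data:
        Threshold records with columns ``carrier_hz`` and ``threshold_ma``
        (one waveform's subset; replicate frequencies allowed).
    free_shape:
        If True, all five parameters are free; by default only ``i0``.

    Returns
    -------
    (params, r_squared):
        Fitted parameters and R^2 of the fit computed on log-thresholds
        (1 - SSE/SST).
    """
    f = np.asarray(data["carrier_hz"], dtype=float)
    y = np.asarray(data["threshold_ma"], dtype=float)
    if np.any(y <= 0):
        raise ValueError("thresholds must be strictly positive")
    if len(np.unique(f)) < 3:
        raise ValueError("at least 3 distinct frequencies are required")
    logy = np.log(y)

    if not free_shape:
        # log I_TH = log i0 + log shape(f): closed-form LS for log i0
        base = ReillyParams(i0=1.0)
        shape = _log_shape(f, base)
        log_i0 = float(np.mean(logy - shape))
        params = ReillyParams(i0=float(np.exp(log_i0)))
        pred = log_i0 + shape
    else:
        def resid(theta):
            p = ReillyParams(
                i0=np.exp(theta[0]),
                high_freq_constant=np.exp(theta[1]),
                high_freq_exponent=theta[2],
                accommodation_constant=np.exp(theta[3]),
                accommodation_exponent=theta[4],
            )
            return np.log(reilly_threshold(f, p)) - logy

        x0 = np.array([np.mean(logy - _log_shape(f, ReillyParams(1.0))),
                       np.log(500.0), 0.9, np.log(10.0), 0.8])
        sol = least_squares(resid, x0, method="lm", max_nfev=5000)
        params = ReillyParams(
            i0=float(np.exp(sol.x[0])),
            high_freq_constant=float(np.exp(sol.x[1])),
            high_freq_exponent=float(sol.x[2]),
            accommodation_constant=float(np.exp(sol.x[3])),
            accommodation_exponent=float(sol.x[4]),
        )
        pred = np.log(reilly_threshold(f, params))

    sse = float(np.sum((logy - pred) ** 2))
    sst = float(np.sum((logy - np.mean(logy)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return params, r2


def validate_threshold_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical threshold-table schema and invariants."""
    missing = [c for c in THRESHOLD_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"threshold table missing columns: {missing}")
    if np.any(data["threshold_ma"] <= 0):
        raise ValueError("thresholds must be strictly positive")
    keys = ["subject", "waveform", "carrier_hz", "amf_hz"]
    if data.duplicated(subset=keys).any():
        raise ValueError("(subject, waveform, frequency, amf) keys must be unique")
    return data


def load_threshold_table(path) -> pd.DataFrame:
    """Read a threshold CSV with the canonical header and validate it."""
    return validate_threshold_table(pd.read_csv(path))
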