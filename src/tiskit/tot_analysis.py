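"""Time-over-threshold (TOT) analysis for interfering kHz carriers.

At a point in tissue driven by two carrier fields with activating-function
amplitudes ``A1`` and ``A2`` offset in frequency by ``delta_f``, the combined
activating function is amplitude modulated with envelope

    env(t) = sqrt(A1**2 + A2**2 + 2*A1*A2*cos(2*pi*delta_f*t))

TOT is the fraction of each modulation (beat) period during which this
envelope is at or above a common activation threshold ``A_T``.  It has a
closed form with three branches:

* ``A1 + A2 < A_T``      -> 0   (never suprathreshold: silent region)
* ``|A1 - A2| > A_T``    -> 1   (always suprathreshold: tonic region)
* otherwise              -> arccos((A_T**2 - A1**2 - A2**2) / (2*A1*A2)) / pi

TOT classifies each point as subthreshold, phasic (beat-locked firing) or
tonic.  A four-electrode interference montage is *bimodal*: tonic regions
near the electrodes coexist with a phasic hotspot between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivatingAmplitudePair",
    "tot_closed_form",
    "tot_oracle",
    "classify_region",
]

#: Values within this distance of an exact 0 or 1 are snapped before
#: classification, so the branch boundaries are not split by round-off.
_SNAP_TOL = 1e-12


@dataclass(frozen=True)
class ActivatingAmplitudePair:
    """Per-carrier activating-function amplitudes at one point.

    Parameters
    ----------
    a1, a2:
        Activating-function amplitudes |d2V/dx2| of the two carriers, V/m^2.
    a_threshold:
        Common activation threshold A_T, V/m^2 (strictly positive).
    """

    a1: float
    a2: float
    a_threshold: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("activating amplitudes must be non-negative")
        if self.a_threshold <= 0:
            raise ValueError("a_threshold must be strictly positive")


def tot_closed_form(pair: ActivatingAmplitudePair) -> float:
    """Closed-form fraction of the beat period spent at or above threshold."""
    a1, a2, at = pair.a1, pair.a2, pair.a_threshold
    if a1 + a2 < at:
        return 0.0
    if abs(a1 - a2) > at:
        return 1.0
    # Constant envelope (a1*a2 == 0) is fully handled by the outer branches;
    # reaching here with a1*a2 == 0 means env == at identically -> over.
    if a1 * a2 == 0.0:
        return 1.0
    arg = (at * at - a1 * a1 - a2 * a2) / (2.0 * a1 * a2)
    arg = min(1.0, max(-1.0, arg))
    return float(np.arccos(arg) / np.pi)


def tot_closed_form_array(
    a1: np.ndarray, a2: np.ndarray, a_threshold: float
) -> np.ndarray:
    """Vectorised :func:`tot_closed_form` for co-registered amplitude maps."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError(f"mismatched grids: {a1.shape} vs {a2.shape}")
    if a_threshold <= 0:
        raise ValueError("a_threshold must be strictly positive")
    at = float(a_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (at * at - a1 * a1 - a2 * a2) / (2.0 * a1 * a2)
    arg = np.clip(arg, -1.0, 1.0)
    tot = np.arccos(arg) / np.pi
    tot = np.where(a1 + a2 < at, 0.0, tot)
    tot = np.where(np.abs(a1 - a2) > at, 1.0, tot)
    # constant-envelope points (a1*a2 == 0) not caught above sit exactly at
    # threshold -> counted as over
    tot = np.where((a1 * a2 == 0.0) & (a1 + a2 >= at) & ~(np.abs(a1 - a2) > at), 1.0, tot)
    return tot


def tot_oracle(
    pair: ActivatingAmplitudePair, delta_f: float = 1.0, n_samples: int = 10_000
) -> float:
    """Brute-force TOT: densely sample the beat envelope over one period.

    Independent of the closed form; counts samples whose envelope is >= A_T.
    The result does not depend on ``delta_f`` (it only rescales time).
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a dense oracle")
    if delta_f <= 0:
        raise ValueError("delta_f must be positive")
    t = np.arange(n_samples) / n_samples / delta_f
    env = np.sqrt(
        pair.a1**2
        + pair.a2**2
        + 2.0 * pair.a1 * pair.a2 * np.cos(2.0 * np.pi * delta_f * t)
    )
    return float(np.mean(env >= pair.a_threshold))


def classify_region(tot: float) -> str:
    """Map a TOT value to ``subthreshold`` (0), ``tonic`` (1) or ``phasic``."""
    if not (0.0 <= tot <= 1.0):
        raise ValueError(f"tot must lie in [0, 1], got {tot!r}")
    if tot <= _SNAP_TOL:
        return "subthreshold"
    if tot >= 1.0 - _SNAP_TOL:
        return "tonic"
    return "phasic"
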