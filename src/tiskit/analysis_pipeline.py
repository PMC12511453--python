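"""Study-level summaries: Reilly fits, threshold ratios, AMF normalization.

These are the summary computations a threshold study reports:

* per-waveform Reilly fits of the pooled strength-frequency means;
* mean threshold ratio +/- SEM between waveforms, computed on matched
  (subject, frequency) pairs ("on average across frequencies");
* per-subject i/i_min normalization of AMF (beat-frequency) curves, then
  averaged across subjects per AMF.

Inferential statistics (mixed models, post-hoc comparisons) are left to
external tools; the generated CSV tables carry everything they need.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .strength_frequency import fit_reilly, validate_threshold_table
from .synthetic_data import (
    SyntheticStudyConfig,
    generate_sf_dataset,
    generate_amf_dataset,
)

__all__ = [
    "StudyReport",
    "threshold_ratios",
    "normalize_amf_curve",
    "run_study",
]


@dataclass(frozen=True)
class StudyReport:
    """Summary of one (synthetic) threshold study."""

    fits: dict  # waveform -> {"i0": mA, "r_squared": float}
    ratios: dict  # "num/den" -> {"mean": float, "sem": float, "n": int}
    amf_curve: dict | None  # amf_hz -> mean i/i_min, if an AMF design ran
    config_hash: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        lines = ["Study report", "============"]
        for w, fit in self.fits.items():
            lines.append(
                f"  {w:>6}: I0 = {fit['i0']:.4g} mA, R^2 = {fit['r_squared']:.4f}"
            )
        for k, r in self.ratios.items():
            lines.append(
                f"  {k}: {r['mean']:.3f} +/- {r['sem']:.3f} (n = {r['n']})"
            )
        if self.amf_curve:
            lines.append("  normalized AMF curve (mean i/i_min):")
            for amf, v in self.amf_curve.items():
                lines.append(f"    AMF {float(amf):g} Hz: {v:.3f}")
        return "\n".join(lines)


def threshold_ratios(
    data: pd.DataFrame,
    numerator: str,
    denominator: str,
    pool: str = "pairs",
) -> tuple[float, float, int]:
    """Mean threshold ratio +/- SEM between two waveforms.

    Ratios are formed on matched (subject, carrier frequency, AMF) keys.
    ``pool="pairs"`` (default) averages over all matched pairs;
    ``pool="frequency"`` first averages per frequency, then across
    frequencies.

    Returns ``(mean, sem, n)`` where ``n`` is the number of pooled values.
    """
    keys = ["subject", "carrier_hz", "amf_hz"]
    for w in (numerator, denominator):
        if w not in set(data["waveform"]):
            raise ValueError(f"waveform {w!r} not present in the data")
    num = data[data["waveform"] == numerator].set_index(keys)["threshold_ma"]
    den = data[data["waveform"] == denominator].set_index(keys)["threshold_ma"]
    joined = pd.concat([num.rename("num"), den.rename("den")], axis=1, join="inner")
    if joined.empty:
        raise ValueError(
            f"no matched (subject, frequency) pairs between {numerator!r} "
            f"and {denominator!r}"
        )
    ratios = joined["num"] / joined["den"]
    if pool == "frequency":
        ratios = ratios.groupby(level="carrier_hz").mean()
    elif pool != "pairs":
        raise ValueError("pool must be 'pairs' or 'frequency'")
    vals = ratios.to_numpy(dtype=float)
    n = len(vals)
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def normalize_amf_curve(data: pd.DataFrame) -> pd.Series:
    """Per-AMF mean of per-subject i/i_min normalized thresholds.

    Each subject's thresholds are divided by that subject's minimum across
    AMFs, then averaged across subjects per AMF.  Because subjects place
    their minima at different AMFs, the averaged curve generally exceeds 1
    everywhere.
    """
    counts = data.groupby("subject")["amf_hz"].nunique()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"subjects with fewer than 2 AMF points: {bad}")
    norm = data.copy()
    norm["i_norm"] = norm.groupby("subject")["threshold_ma"].transform(
        lambda x: x / x.min()
    )
    return norm.groupby("amf_hz")["i_norm"].mean()


def _config_hash(cfg: SyntheticStudyConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_study(
    cfg: SyntheticStudyConfig,
    amf_grid=None,
    ratio_pairs: tuple = (("am", "sine"), ("burst", "sine")),
) -> StudyReport:
    """Generate a study, fit it, and summarize: a pure function of config.

    Fits the Reilly equation to each waveform's pooled per-frequency
    geometric-mean thresholds; computes the requested waveform threshold
    ratios; and, when ``amf_grid`` is given, also runs the AMF design and
    reports the normalized i/i_min curve.
    """
    try:
        data = validate_threshold_table(generate_sf_dataset(cfg))
    except ValueError as e:
        raise ValueError(f"[generate] {e}") from e

    fits = {}
    for w in cfg.waveforms:
        sub = data[data["waveform"] == w]
        pooled = (
            sub.groupby("carrier_hz")["threshold_ma"]
            .apply(lambda x: float(np.exp(np.mean(np.log(x)))))
            .reset_index()
        )
        try:
            params, r2 = fit_reilly(pooled)
        except ValueError as e:
            raise ValueError(f"[fit:{w}] {e}") from e
        fits[w] = {"i0": params.i0, "r_squared": r2}

    ratios = {}
    for numw, denw in ratio_pairs:
        try:
            mean, sem, n = threshold_ratios(data, numw, denw)
        except ValueError as e:
            raise ValueError(f"[ratios:{numw}/{denw}] {e}") from e
        ratios[f"{numw}/{denw}"] = {"mean": mean, "sem": sem, "n": n}

    amf_curve = None
    if amf_grid is not None:
        try:
            amf_data = generate_amf_dataset(cfg, amf_grid)
            curve = normalize_amf_curve(amf_data)
        except ValueError as e:
            raise ValueError(f"[amf] {e}") from e
        amf_curve = {str(k): float(v) for k, v in curve.items()}

    return StudyReport(
        fits=fits,
        ratios=ratios,
        amf_curve=amf_curve,
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
    )
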