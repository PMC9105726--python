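"""Evaluation metrics: SNR in dB, relative error, correlation coefficient,
localization distance, and the intrinsic-noise crossover calculus.

Conventions
-----------
* SNR = 20 log10(RMS_signal / RMS_noise), with RMS_signal taken from the
  noise-free simulated map and RMS_noise from the realized noise map of the
  same sample.
* RE = sqrt( mean((B_s - B_r)^2) / mean(B_r^2) ): the denominator is the
  RECONSTRUCTED map's power.  The convention is asymmetric and is kept
  exactly as defined (a regression test pins the denominator).
* CC is the Pearson correlation over channels.
* d_s,f compares dipole POSITIONS only; orientation and amplitude errors
  are not part of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forward_sphere import Dipole, FieldMap

__all__ = [
    "MetricSet",
    "rms",
    "snr_db",
    "relative_error",
    "correlation_coefficient",
    "localization_error",
    "intrinsic_noise_crossover",
    "noise_inflation_factor",
]


@dataclass(frozen=True)
class MetricSet:
    """The evaluation quantities for one fitted sample.  Unavailable
    entries (e.g. SNR when no noise was added) are NaN."""

    snr_db: float
    re: float
    cc: float
    d_sf: float  # m
    rms_signal: float  # T
    rms_noise: float  # T

    def __post_init__(self) -> None:
        if not math.isnan(self.re) and self.re < 0:
            raise ValueError("re must be >= 0")
        if not math.isnan(self.cc) and not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise ValueError("cc must lie in [-1, 1]")
        if not math.isnan(self.d_sf) and self.d_sf < 0:
            raise ValueError("d_sf must be >= 0")


def _values(B) -> np.ndarray:
    return B.values if isinstance(B, FieldMap) else np.asarray(B, dtype=float)


def rms(B) -> float:
    """Root mean square over channels."""
    v = _values(B)
    if v.size == 0:
        raise ValueError("rms of an empty field map is undefined")
    return float(np.sqrt(np.mean(v**2)))


def snr_db(rms_signal: float, rms_noise: float) -> float:
    """20 log10(RMS_signal / RMS_noise) in dB."""
    if rms_noise <= 0:
        raise ValueError("rms_noise must be > 0 for a finite SNR")
    if rms_signal < 0:
        raise ValueError("rms_signal must be >= 0")
    return 20.0 * math.log10(rms_signal / rms_noise)


def relative_error(B_s, B_r) -> float:
    """sqrt( mean((B_s - B_r)^2) / mean(B_r^2) ); denominator is the
    reconstructed map B_r."""
    s, r = _values(B_s), _values(B_r)
    if s.shape != r.shape:
        raise ValueError("field maps must have equal length")
    denom = np.mean(r**2)
    if denom == 0:
        raise ValueError("relative error undefined for an all-zero reconstruction")
    return float(np.sqrt(np.mean((s - r) ** 2) / denom))


def correlation_coefficient(B_s, B_r) -> float:
    """Pearson correlation over channels."""
    s, r = _values(B_s), _values(B_r)
    if s.shape != r.shape:
        raise ValueError("field maps must have equal length")
    if s.size < 2:
        raise ValueError("correlation needs at least 2 channels")
    ds, dr = s - s.mean(), r - r.mean()
    ns, nr = np.linalg.norm(ds), np.linalg.norm(dr)
    if ns == 0 or nr == 0:
        raise ValueError("correlation undefined for a constant field map")
    return float(np.clip((ds @ dr) / (ns * nr), -1.0, 1.0))


def localization_error(true: Dipole, fitted: Dipole) -> float:
    """Euclidean distance d_s,f between the two dipole positions (m)."""
    return float(np.linalg.norm(true.position - fitted.position))


def intrinsic_noise_crossover(
    signal_gain: float, intrinsic_a: float, intrinsic_b: float
) -> float:
    """Ambient-noise level at which the two systems' SNRs are equal.

    System A measures ``signal_gain`` times the signal of system B but has
    the larger intrinsic sensor noise ``intrinsic_a``; system B has
    ``intrinsic_b``.  Intrinsic noise combines with ambient noise by summing
    variances, so the SNRs cross where

        signal_gain / sqrt(sigma^2 + a^2) = 1 / sqrt(sigma^2 + b^2),

    i.e. sigma = sqrt( (a^2 - g^2 b^2) / (g^2 - 1) ).  Units follow the
    inputs (typically fT).  Below the returned sigma the low-intrinsic-noise
    system wins; above it the high-gain system wins.
    """
    g = float(signal_gain)
    if g <= 1:
        raise ValueError("signal_gain must exceed 1")
    if intrinsic_a <= g * intrinsic_b:
        raise ValueError("no crossover: intrinsic_a must exceed signal_gain * intrinsic_b")
    return math.sqrt((intrinsic_a**2 - g**2 * intrinsic_b**2) / (g**2 - 1.0))


def noise_inflation_factor(sigma: float, intrinsic: float) -> float:
    """Factor by which intrinsic sensor noise inflates the total noise SD at
    ambient level ``sigma``: sqrt(sigma^2 + intrinsic^2) / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return math.sqrt(sigma**2 + intrinsic**2) / sigma
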