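"""Minimum-jerk reference trajectories and the SPARC smoothness metric.

SPARC (spectral arc length) measures movement smoothness as the negative
arc length of the normalized Fourier magnitude spectrum of a velocity
profile, evaluated up to an adaptive cutoff frequency. It is
dimensionless, amplitude- and duration-normalized, and always <= 0; more
negative values mean a less smooth movement. A minimum-jerk trajectory
(MJT) — the maximally smooth point-to-point profile
``x(t) = A (10 tau^3 - 15 tau^4 + 6 tau^5)`` — serves as the smoothness
upper bound: for typical arm-elevation durations its SPARC is about
-1.4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: default SPARC parameters (the metric's reference parametrisation)
SPARC_MAX_CUTOFF_HZ = 10.0
SPARC_AMP_THRESHOLD = 0.05
SPARC_PAD_LEVEL = 4


@dataclass
class SmoothnessResult:
    """SPARC value of one movement phase, with the parameters used."""

    phase: str  # "ascent" | "descent"
    sparc: float
    max_cutoff_hz: float = SPARC_MAX_CUTOFF_HZ
    amp_threshold: float = SPARC_AMP_THRESHOLD
    pad_level: int = SPARC_PAD_LEVEL
    event: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sparc > 0:
            raise ValueError("SPARC is non-positive by construction")


def minimum_jerk_trajectory(
    amplitude: float, duration: float, rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk point-to-point profile.

    Parameters
    ----------
    amplitude : float
        Total excursion A (degrees, or any unit).
    duration : float
        Movement time T in seconds.
    rate : float
        Sample rate in Hz.

    Returns
    -------
    t, x, v : ndarray
        Time (s), position ``A (10 tau^3 - 15 tau^4 + 6 tau^5)`` and
        velocity per second, with zero velocity and acceleration at both
        endpoints and peak velocity ``1.875 A / T`` at mid-movement.
    """
    if amplitude <= 0 or duration <= 0 or rate <= 0:
        raise ValueError("amplitude, duration and rate must be positive")
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    tau = t / duration
    x = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    v = amplitude / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return t, x, v


def sparc(
    velocity: np.ndarray,
    rate: float,
    max_cutoff: float = SPARC_MAX_CUTOFF_HZ,
    amp_threshold: float = SPARC_AMP_THRESHOLD,
    pad_level: int = SPARC_PAD_LEVEL,
) -> float:
    """Spectral arc length of a velocity profile.

    The magnitude spectrum of the (zero-padded) velocity profile is
    normalized to its maximum; the spectrum is kept up to ``max_cutoff``
    and then trimmed to the band where the normalized magnitude exceeds
    ``amp_threshold`` (the adaptive cutoff). SPARC is the negative arc
    length of the trimmed spectrum with the frequency axis normalized by
    the cutoff, so the metric is invariant to amplitude scaling.

    Raises
    ------
    ValueError
        On an empty or all-zero velocity profile.
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity profile")
    if not np.any(v != 0):
        raise ValueError("all-zero velocity profile has no spectrum to measure")

    nfft = int(2 ** np.ceil(np.log2(len(v)) + pad_level))
    freqs = np.arange(nfft) * (rate / nfft)
    mag = np.abs(np.fft.fft(v, nfft))
    mag = mag / mag.max()

    below = freqs <= max_cutoff
    f_sel, m_sel = freqs[below], mag[below]
    above = np.nonzero(m_sel >= amp_threshold)[0]
    lo, hi = above[0], above[-1] + 1
    f_sel, m_sel = f_sel[lo:hi], m_sel[lo:hi]

    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    dm = np.diff(m_sel)
    return float(-np.sum(np.sqrt(df**2 + dm**2)))


def phase_smoothness(
    velocity: np.ndarray,
    rate: float,
    phase: str,
    event: Optional[str] = None,
    **params,
) -> SmoothnessResult:
    """SPARC of one segmented movement phase, parameters recorded."""
    value = sparc(velocity, rate, **params)
    return SmoothnessResult(
        phase=phase,
        sparc=value,
        max_cutoff_hz=params.get("max_cutoff", SPARC_MAX_CUTOFF_HZ),
        amp_threshold=params.get("amp_threshold", SPARC_AMP_THRESHOLD),
        pad_level=params.get("pad_level", SPARC_PAD_LEVEL),
        event=event,
    )
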