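"""Filtering, movement segmentation and repetition selection.

Angle series are low-pass filtered (zero-phase Butterworth, 5 Hz) before
velocity-threshold segmentation. Range-of-motion segmentation finds
ascent-hold-descent elevation events at a 7 deg/s threshold on the
gravitational-elevation velocity; functional-task segmentation splits a
single elevation into ascent, hold and descent phases at 10 deg/s. Per
study block and target direction only the second elevation enters the
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from scapkin.kinematics import AngleSeries

logger = logging.getLogger(__name__)

ROM_VELOCITY_THRESHOLD = 7.0  # deg/s, elevation-event segmentation
FUNCTIONAL_VELOCITY_THRESHOLD = 10.0  # deg/s, ascent/hold/descent split
LOWPASS_CUTOFF_HZ = 5.0
MIN_RUN_DURATION_S = 0.25  # guard against threshold chatter


@dataclass
class ElevationEvent:
    """One segmented arm raise (frame indices into its angle series)."""

    ascent_start: int
    hold_start: int
    hold_end: int
    descent_end: int
    peak_frame: int
    peak_theta_g: float
    peak_kappa: float
    peak_theta: float
    direction: Optional[str] = None
    condition: Optional[str] = None
    trial: Optional[str] = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        if not (
            self.ascent_start <= self.hold_start <= self.hold_end <= self.descent_end
        ):
            raise ValueError("event phase boundaries out of order")
        if not self.ascent_start <= self.peak_frame <= self.descent_end:
            raise ValueError("peak frame outside event boundaries")


def lowpass(x: np.ndarray, rate: float, cutoff: float = LOWPASS_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass filter.

    NaN-free segments are required; the series must exceed the filtfilt
    warm-up length (about 19 samples for order 4).
    """
    x = np.asarray(x, dtype=float)
    if rate <= 2 * cutoff:
        raise ValueError("sample rate must exceed twice the cutoff")
    b, a = butter(4, cutoff / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"series of length {len(x)} shorter than filter warm-up {padlen + 1}")
    return filtfilt(b, a, x)


def angular_velocity(x: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference velocity (deg/s) of a filtered angle series."""
    return np.gradient(np.asarray(x, dtype=float)) * rate


def lowpass_with_flags(x: np.ndarray, rate: float, cutoff: float = LOWPASS_CUTOFF_HZ) -> np.ndarray:
    """Low-pass a series containing flagged (NaN) frames.

    Flagged frames are bridged linearly only to keep the filter stable
    and are restored to NaN afterwards, so no interpolated value ever
    leaves this function.
    """
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if ok.all():
        return lowpass(x, rate, cutoff)
    if ok.sum() < 2:
        raise ValueError("too few finite samples to filter")
    logger.debug("bridging %d flagged frames for filtering", int((~ok).sum()))
    filled = np.interp(np.arange(len(x)), np.flatnonzero(ok), x[ok])
    y = lowpass(filled, rate, cutoff)
    y[~ok] = np.nan
    return y


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def segment_rom(
    velocity: np.ndarray,
    rate: float,
    threshold: float = ROM_VELOCITY_THRESHOLD,
    min_duration: float = MIN_RUN_DURATION_S,
) -> list[tuple[int, int, int, int]]:
    """Segment elevation events from a theta_g velocity profile.

    Maximal runs with ``|velocity| >= threshold`` lasting at least
    ``min_duration`` are classified as ascent (positive mean velocity)
    or descent (negative); each ascent is merged with the next descent
    across the intervening hold into one ascent-hold-descent event.

    Returns
    -------
    list of (ascent_start, hold_start, hold_end, descent_end)
        Frame indices; empty list if no event is found.
    """
    v = np.asarray(velocity, dtype=float)
    guard = int(np.ceil(min_duration * rate))
    runs = [(a, b) for a, b in _runs(np.abs(v) >= threshold) if b - a >= guard]
    events: list[tuple[int, int, int, int]] = []
    pending: Optional[tuple[int, int]] = None
    for a, b in runs:
        if np.nanmean(v[a:b]) > 0:
            if pending is not None:
                logger.warning("ascent run without matching descent dropped")
            pending = (a, b)
        elif pending is not None:
            events.append((pending[0], pending[1], a, b))
            pending = None
    if pending is not None:
        logger.warning("trailing ascent run without descent dropped")
    return events


def extract_elevations(
    angles: AngleSeries,
    direction: Optional[str] = None,
    condition: Optional[str] = None,
    trial: Optional[str] = None,
    threshold: float = ROM_VELOCITY_THRESHOLD,
    prefiltered: bool = False,
) -> list[ElevationEvent]:
    """Low-pass filter theta_g, segment it, and build elevation events.

    The peak frame is the theta_g maximum within each event; kappa and
    theta are evaluated at that frame (peak theta = peak theta_g minus
    kappa at the peak frame).
    """
    if prefiltered:
        tg, kp = angles.theta_g, angles.kappa
    else:
        tg = lowpass(angles.theta_g, angles.sample_rate)
        kp = lowpass_with_flags(angles.kappa, angles.sample_rate)
    v = angular_velocity(tg, angles.sample_rate)
    events = []
    for a0, h0, h1, d1 in segment_rom(v, angles.sample_rate, threshold=threshold):
        peak = a0 + int(np.argmax(tg[a0:d1]))
        kappa_pk = float(kp[peak])
        events.append(
            ElevationEvent(
                ascent_start=a0,
                hold_start=h0,
                hold_end=h1,
                descent_end=d1,
                peak_frame=peak,
                peak_theta_g=float(tg[peak]),
                peak_kappa=kappa_pk,
                peak_theta=float(tg[peak]) - kappa_pk,
                direction=direction,
                condition=condition,
                trial=trial,
            )
        )
    return events


def segment_functional(
    velocity: np.ndarray,
    rate: float,
    threshold: float = FUNCTIONAL_VELOCITY_THRESHOLD,
    min_duration: float = MIN_RUN_DURATION_S,
) -> tuple[slice, slice, slice, bool]:
    """Split one elevation into ascent, hold and descent phases.

    Ascent is the first sustained run with velocity above ``+threshold``,
    descent the last sustained run below ``-threshold``; the hold spans
    the frames in between. Returns (ascent, hold, descent, incomplete);
    ``incomplete`` is True when no descent exists (monotone ascent).

    Raises
    ------
    ValueError
        If no super-threshold motion is present.
    """
    v = np.asarray(velocity, dtype=float)
    guard = int(np.ceil(min_duration * rate))
    up = [(a, b) for a, b in _runs(v > threshold) if b - a >= guard]
    down = [(a, b) for a, b in _runs(v < -threshold) if b - a >= guard]
    if not up:
        raise ValueError("no super-threshold ascent motion")
    a0, a1 = up[0]
    if not down or down[-1][0] < a1:
        logger.warning("no descent found: event flagged incomplete")
        return slice(a0, a1), slice(a1, len(v)), slice(len(v), len(v)), True
    d0, d1 = down[-1]
    return slice(a0, a1), slice(a1, d0), slice(d0, d1), False


def select_analysed_elevation(events: Sequence[ElevationEvent]) -> ElevationEvent:
    """Pick the analysed repetition: the second elevation of the block.

    Falls back to the only elevation (with a warning) when a single one
    was segmented; raises on an empty list.
    """
    if len(events) == 0:
        raise ValueError("no elevation events to select from")
    if len(events) == 1:
        logger.warning("only one elevation found; analysing it instead of the second")
        return events[0]
    return events[1]
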