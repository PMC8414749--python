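"""Segment reconstruction and the study's angle system.

The angle system describes an arm elevation with respect to gravity:

- ``theta_g`` — gravitational elevation: angle between the wrist vector
  (shoulder -> wrist) and the gravity vector; 0 deg = arm hanging,
  180 deg = overhead.
- ``kappa`` — trunk compensation: change of the sternum-vs-gravity angle
  relative to the initial posture, projected onto the plane of elevation;
  positive when the lean carries the arm toward larger theta_g.
- ``theta = theta_g - kappa`` — elevation corrected for trunk lean.
- ``alpha`` — plane-of-elevation azimuth: angle between the horizontal
  projections of the initial acromion-to-acromion line and the
  glenoid -> wrist line (0 deg = pure sideward reach, 90 deg = straight
  forward; flexion target 80 deg, abduction target 30 deg).
- ``rho`` — scapular rotation: angle of the scapular medial border with
  respect to the gravity vector, signed in the plane of elevation
  (negative = medial winging).
- ``theta_gh = theta_g - rho`` — glenohumeral elevation.

The ScAla (scapula alata) score 1:x is the slope x of ``rho`` against
``theta_gh`` over an ascent; 1:0.5 is the physiological scapulohumeral
rhythm, negative x indicates medial winging.

Frames where a horizontal projection is degenerate (arm within ~1 deg of
vertical) are flagged and excluded from plane-dependent angles, never
interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from scapkin.frame import GRAVITY_DIR, UP
from scapkin.mocap_io import MarkerFrameSeries

logger = logging.getLogger(__name__)

#: markers required to reconstruct thorax, shoulder and wrist
REQUIRED_MARKERS = ("IJ", "PX", "C7", "T8", "RACR", "LACR", "RRS", "RUS")
#: full study marker set (epicondyles complete the 10-marker protocol)
STUDY_MARKERS = REQUIRED_MARKERS + ("RLE", "RME")
#: optional synthetic annotation markers tracing the scapular medial border
SCAPULA_MARKERS = ("RSCAP_SUP", "RSCAP_INF")

#: caudal offset (mm) from the acromion marker to the glenohumeral centre
GH_OFFSET_MM = 30.0
#: sin(elevation) below which the horizontal projection of the wrist
#: vector is treated as degenerate
_HORIZ_TOL = np.sin(np.deg2rad(1.0))


@dataclass
class SegmentFrames:
    """Per-frame body-segment geometry reconstructed from markers."""

    times: np.ndarray
    sample_rate: float
    sternum_axis: np.ndarray  # (n,3) unit, cranial
    shoulder: np.ndarray  # (n,3) mm
    wrist: np.ndarray  # (n,3) mm
    acromia_line: np.ndarray  # (n,3) unit, right -> left
    scapula_axis: Optional[np.ndarray] = None  # (n,3) unit, superior -> inferior
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)


@dataclass
class AngleSeries:
    """Per-frame angle system of one trial (degrees)."""

    times: np.ndarray
    sample_rate: float
    theta_g: np.ndarray
    kappa: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    rho: Optional[np.ndarray] = None
    theta_gh: Optional[np.ndarray] = None
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    """True where plane-dependent angles are undefined for that frame."""

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("theta_g", "kappa", "theta", "alpha"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch with time base")
        if self.flags is None:
            self.flags = np.zeros(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def reconstruct_segments(m: MarkerFrameSeries) -> SegmentFrames:
    """Build thorax, shoulder and wrist geometry from the marker set.

    The sternum longitudinal axis runs from the midpoint of the caudal
    thorax markers (PX, T8) to the midpoint of the cranial ones (IJ, C7),
    pointing cranially. The wrist point is the styloid midpoint; the
    shoulder (glenohumeral) point is the right acromion offset
    ``GH_OFFSET_MM`` caudally along the sternum axis; the glenoid is
    approximated by the same point.
    """
    for name in REQUIRED_MARKERS:
        if name not in m.markers:
            raise ValueError(f"required marker {name!r} missing from series")

    valid = np.ones(m.n_frames, dtype=bool)
    for name in REQUIRED_MARKERS:
        valid &= ~m.gaps[name]

    ij, c7 = m.markers["IJ"], m.markers["C7"]
    px, t8 = m.markers["PX"], m.markers["T8"]
    cranial_mid = 0.5 * (ij + c7)
    caudal_mid = 0.5 * (px + t8)
    axis_vec = cranial_mid - caudal_mid
    axis_len = np.linalg.norm(axis_vec, axis=1)
    acromia_vec = m.markers["LACR"] - m.markers["RACR"]
    acr_len = np.linalg.norm(acromia_vec, axis=1)
    degenerate = valid & ((axis_len < 1.0) | (acr_len < 1.0))
    if np.any(degenerate):
        raise ValueError("degenerate thorax geometry: coincident markers")

    with np.errstate(invalid="ignore", divide="ignore"):
        sternum_axis = axis_vec / axis_len[:, None]
        acromia_line = acromia_vec / acr_len[:, None]
    shoulder = m.markers["RACR"] - GH_OFFSET_MM * sternum_axis
    wrist = 0.5 * (m.markers["RRS"] + m.markers["RUS"])
    wrist_len = np.linalg.norm(wrist - shoulder, axis=1)
    if np.any(valid & (wrist_len < 1.0)):
        raise ValueError("degenerate arm geometry: wrist coincides with shoulder")

    scapula_axis = None
    if all(name in m.markers for name in SCAPULA_MARKERS):
        sup, inf = m.markers["RSCAP_SUP"], m.markers["RSCAP_INF"]
        valid_sc = ~(m.gaps["RSCAP_SUP"] | m.gaps["RSCAP_INF"])
        border = inf - sup
        blen = np.linalg.norm(border, axis=1)
        if np.any(valid_sc & (blen < 1.0)):
            raise ValueError("degenerate scapula border markers")
        with np.errstate(invalid="ignore", divide="ignore"):
            scapula_axis = border / blen[:, None]
        valid &= valid_sc

    return SegmentFrames(
        times=m.times,
        sample_rate=m.sample_rate,
        sternum_axis=sternum_axis,
        shoulder=shoulder,
        wrist=wrist,
        acromia_line=acromia_line,
        scapula_axis=scapula_axis,
        valid=valid,
    )


def elevation_angle_gravity(
    shoulder: np.ndarray, wrist: np.ndarray, gravity_dir: np.ndarray = GRAVITY_DIR
) -> np.ndarray:
    """Gravitational elevation theta_g in degrees.

    Angle between the wrist vector (shoulder -> wrist) and the gravity
    direction: 0 deg with the arm hanging, 180 deg overhead.
    """
    sw = np.atleast_2d(wrist) - np.atleast_2d(shoulder)
    norms = np.linalg.norm(sw, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length wrist vector")
    g = np.asarray(gravity_dir, dtype=float)
    g = g / np.linalg.norm(g)
    cosang = np.clip(sw @ g / norms, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    return out if np.ndim(wrist) == 2 else float(out[0])


def plane_of_elevation(shoulder: np.ndarray, wrist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal in-plane direction of the plane of elevation.

    The plane of elevation is spanned by the wrist vector and gravity;
    its horizontal trace (unit vector ``u``) orients all plane-projected
    angles. Frames where the wrist vector is within ~1 deg of vertical
    have no defined plane and are flagged.

    Returns
    -------
    u : ndarray, shape (n, 3)
        Horizontal unit vector in the plane (NaN where flagged).
    flagged : ndarray of bool, shape (n,)
    """
    sw = np.atleast_2d(wrist) - np.atleast_2d(shoulder)
    norms = np.linalg.norm(sw, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length wrist vector")
    horiz = sw - np.outer(sw @ UP, UP)
    hnorm = np.linalg.norm(horiz, axis=1)
    flagged = hnorm < _HORIZ_TOL * norms
    u = np.full_like(horiz, np.nan)
    ok = ~flagged
    u[ok] = horiz[ok] / hnorm[ok, None]
    return u, flagged


def alpha_plane(acromia_line_initial: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Plane-of-elevation angle alpha in degrees.

    Angle between the horizontal projections of the initial acromion line
    and the glenoid -> wrist line. The acromion line is taken toward the
    instrumented (right) side so that a pure sideward reach gives 0 deg,
    straight forward 90 deg and a cross-body reach up to 180 deg.

    ``u`` is the horizontal in-plane direction from
    :func:`plane_of_elevation` (NaN rows propagate to NaN alpha).
    """
    a = np.asarray(acromia_line_initial, dtype=float)
    a_h = a - (a @ UP) * UP
    if np.linalg.norm(a_h) < 1e-9:
        raise ValueError("acromia line has no horizontal projection")
    toward_right = -a_h / np.linalg.norm(a_h)  # acromia line is right -> left
    u2 = np.atleast_2d(u)
    cosang = np.clip(u2 @ toward_right, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    return out if np.ndim(u) == 2 else float(out[0])


def _inplane_angle(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Polar angle (deg) of the projection of ``v`` in the (u, UP) plane."""
    v2, u2 = np.atleast_2d(v), np.atleast_2d(u)
    comp_u = np.sum(v2 * u2, axis=1)
    comp_z = v2 @ UP
    return np.degrees(np.arctan2(comp_z, comp_u))


def trunk_compensation(
    sternum_axis: np.ndarray, sternum_axis_initial: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Trunk compensation kappa in degrees.

    Both sternum axes are projected onto the plane of elevation (spanned
    by ``u`` and the vertical); kappa is the signed angle between the
    projections, positive when the trunk rotation carries the arm toward
    larger theta_g (lean away from the reach direction). Frames whose
    projection is degenerate come out NaN.
    """
    s_now = np.atleast_2d(sternum_axis)
    u2 = np.atleast_2d(u)
    s0 = np.asarray(sternum_axis_initial, dtype=float)
    proj_now = np.hypot(np.sum(s_now * u2, axis=1), s_now @ UP)
    proj_init = np.hypot(np.sum(s0 * u2, axis=1), s0 @ UP)
    ang_now = _inplane_angle(s_now, u2)
    ang_init = _inplane_angle(np.broadcast_to(s0, s_now.shape), u2)
    kappa = ang_now - ang_init
    kappa = (kappa + 180.0) % 360.0 - 180.0
    bad = (proj_now < 1e-6) | (proj_init < 1e-6)
    kappa = np.where(bad, np.nan, kappa)
    return kappa if np.ndim(sternum_axis) == 2 else float(kappa[0])


def corrected_elevation(theta_g: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """theta = theta_g - kappa, element-wise (degrees)."""
    theta_g, kappa = np.asarray(theta_g, float), np.asarray(kappa, float)
    if theta_g.shape != kappa.shape:
        raise ValueError("theta_g and kappa length mismatch")
    return theta_g - kappa


def glenohumeral_elevation(theta_g: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """theta_GH = theta_g - rho, element-wise (degrees)."""
    theta_g, rho = np.asarray(theta_g, float), np.asarray(rho, float)
    if theta_g.shape != rho.shape:
        raise ValueError("theta_g and rho length mismatch")
    return theta_g - rho


def scapular_rotation(scapula_axis: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Scapular rotation rho in degrees from the medial-border axis.

    rho is the angle of the (superior -> inferior) border axis with
    respect to the gravity vector, signed positive when the inferior
    angle swings toward the reach direction ``u`` (lateral/upward
    rotation) and negative for medial winging.
    """
    b = np.atleast_2d(scapula_axis)
    u2 = np.atleast_2d(u)
    comp_u = np.sum(b * u2, axis=1)
    comp_down = -(b @ UP)
    rho = np.degrees(np.arctan2(comp_u, comp_down))
    return rho if np.ndim(scapula_axis) == 2 else float(rho[0])


def scala_score(
    theta_gh: np.ndarray,
    rho: np.ndarray,
    min_range_deg: float = 20.0,
) -> float:
    """ScAla score slope x of the ratio 1:x over an ascent.

    Least-squares slope of scapular rotation ``rho`` against
    glenohumeral elevation ``theta_gh``; 0.5 is the physiological
    scapulohumeral rhythm, negative values indicate medial winging.
    NaN frames are dropped pairwise.

    Raises
    ------
    ValueError
        If the ascent covers less than ``min_range_deg`` of theta_gh.
    """
    theta_gh = np.asarray(theta_gh, float)
    rho = np.asarray(rho, float)
    ok = np.isfinite(theta_gh) & np.isfinite(rho)
    x, y = theta_gh[ok], rho[ok]
    if len(x) < 2 or np.ptp(x) < min_range_deg:
        raise ValueError(
            f"insufficient elevation range for ScAla score: need >= {min_range_deg} deg"
        )
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def scala_score_single_frame(theta_gh: float, rho: float) -> float:
    """Single-frame ScAla ratio rho/theta_gh (the reference-picture variant)."""
    if theta_gh == 0:
        raise ValueError("theta_gh must be nonzero for a single-frame ratio")
    return float(rho / theta_gh)


def format_scala(x: float) -> str:
    """Render a ScAla slope as the conventional '1:x' string, one decimal."""
    return f"1:{x:.1f}"


def compute_angles(
    m: MarkerFrameSeries,
    rho: Optional[np.ndarray] = None,
    initial_frame: int = 0,
) -> AngleSeries:
    """Full angle system of one trial from its marker series.

    ``rho`` may be supplied externally (e.g. annotated from reference
    pictures); otherwise it is derived from the synthetic scapula border
    markers when present, else left out. The initial frame fixes the
    reference posture: kappa(initial) = 0 and the acromion line of that
    frame anchors alpha.
    """
    seg = reconstruct_segments(m)
    theta_g = elevation_angle_gravity(seg.shoulder, seg.wrist)
    u, flagged = plane_of_elevation(seg.shoulder, seg.wrist)
    flagged = flagged | ~seg.valid

    s0 = seg.sternum_axis[initial_frame]
    a0 = seg.acromia_line[initial_frame]
    kappa = trunk_compensation(seg.sternum_axis, s0, u)
    kappa[flagged] = np.nan
    kappa[initial_frame] = 0.0  # reference posture by definition
    alpha = alpha_plane(a0, u)
    alpha[flagged] = np.nan
    theta = corrected_elevation(theta_g, kappa)

    if rho is None and seg.scapula_axis is not None:
        rho = scapular_rotation(seg.scapula_axis, u)
        rho[flagged] = np.nan
    theta_gh = glenohumeral_elevation(theta_g, rho) if rho is not None else None

    n_flagged = int(np.sum(flagged))
    if n_flagged:
        logger.debug("flagged %d frames with degenerate plane of elevation", n_flagged)
    return AngleSeries(
        times=m.times,
        sample_rate=m.sample_rate,
        theta_g=theta_g,
        kappa=kappa,
        theta=theta,
        alpha=alpha,
        rho=rho,
        theta_gh=theta_gh,
        flags=flagged,
    )
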