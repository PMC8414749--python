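"""Cable-tension to normal-force model for the orthosis tensioning system.

The scapula orthosis presses a plate onto the scapula interface via a
cable routed between the elevated pressure plate and three anchor points
on a thorax harness (an out-and-back pass per anchor, six segments in
total). Because the plate sits proud of the anchors, each cable segment
pulls at an elevation angle to the plate plane and contributes a normal
component pressing the plate down.

The model combines belt (capstan) friction with the segment geometry:
tension in segment k is ``T_k = T0 * exp(-mu * Phi_k)`` where ``Phi_k``
is the cumulative wrap angle over the redirections the cable has passed,
and the effective normal force is ``N = sum_k T_k * sin(phi_k)`` with
``phi_k`` the segment's anchor elevation angle. With ``mu = 0`` this
reduces to the frictionless closed form ``N = T0 * sum_k sin(phi_k)``.

An independent 3D static-equilibrium oracle recomputes N from explicit
plate/anchor coordinates; it exists for validation and tests, never as
the production path. Skin-pressure checks apply the 16 kPa short-term /
4 kPa long-term limits, plus the literature bounds of 100 N anterior and
82 N lateral scapula-stabilising force demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CABLE_FRICTION_MU = 0.1
SHORT_TERM_PRESSURE_LIMIT_PA = 16_000.0
LONG_TERM_PRESSURE_LIMIT_PA = 4_000.0
ANTERIOR_FORCE_BOUND_N = 100.0
LATERAL_FORCE_BOUND_N = 82.0


@dataclass
class PulleyGeometry:
    """Geometry of the cable routing between plate and thorax anchors.

    Parameters
    ----------
    anchor_angles_deg : (3,) floats
        Elevation angles between each thorax anchor point and the
        pressure plate, in (0, 90) degrees.
    n_segments : int
        Even number of cable segments; default 6 = out-and-back per
        anchor, pairing segments (1,2), (3,4), (5,6) with the anchors.
    wrap_angles_rad : floats, length n_segments - 1
        Wrap angle of each redirection the cable passes between
        consecutive segments; default pi/2 each.
    friction_mu : float
        Cable/guide friction coefficient (dimensionless), default 0.1.
    interface_area_m2 : float
        Area of the scapula interface distributing the normal force.
    plate_xyz, anchor_xyz : optional explicit 3D coordinates (metres)
        used only by the equilibrium oracle.
    """

    anchor_angles_deg: Sequence[float] = (30.0, 30.0, 30.0)
    n_segments: int = 6
    wrap_angles_rad: Optional[Sequence[float]] = None
    friction_mu: float = CABLE_FRICTION_MU
    interface_area_m2: float = 0.01
    plate_xyz: Optional[np.ndarray] = None
    anchor_xyz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.anchor_angles_deg = np.asarray(self.anchor_angles_deg, dtype=float)
        if np.any(self.anchor_angles_deg <= 0) or np.any(self.anchor_angles_deg >= 90):
            raise ValueError("anchor angles must lie strictly between 0 and 90 degrees")
        if self.n_segments % 2 or self.n_segments <= 0:
            raise ValueError("segment count must be a positive even number")
        if self.n_segments // 2 != len(self.anchor_angles_deg):
            raise ValueError("need one anchor angle per out-and-back segment pair")
        if self.wrap_angles_rad is None:
            self.wrap_angles_rad = np.full(self.n_segments - 1, np.pi / 2)
        self.wrap_angles_rad = np.asarray(self.wrap_angles_rad, dtype=float)
        if len(self.wrap_angles_rad) != self.n_segments - 1:
            raise ValueError("need one wrap angle per redirection (n_segments - 1)")
        if self.friction_mu < 0:
            raise ValueError("friction coefficient must be non-negative")
        if self.interface_area_m2 <= 0:
            raise ValueError("interface area must be positive")

    @property
    def segment_angles_deg(self) -> np.ndarray:
        """Anchor elevation angle of each of the n_segments segments."""
        return np.repeat(self.anchor_angles_deg, 2)

    def segment_tensions(self, tension_n: float) -> np.ndarray:
        """Capstan-attenuated tension in each segment for cable tension T0."""
        cum_wrap = np.concatenate(([0.0], np.cumsum(self.wrap_angles_rad)))
        return tension_n * np.exp(-self.friction_mu * cum_wrap)


@dataclass
class ForceReading:
    """One cable-tension measurement and its modelled normal force."""

    cable_tension_n: float
    normal_force_n: float
    reference_normal_force_n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cable_tension_n < 0 or self.normal_force_n < 0:
            raise ValueError("tension and normal force must be non-negative")


def normal_force(tension_n: float, g: PulleyGeometry) -> float:
    """Effective normal force N on the scapula interface for cable tension T0.

    ``N = sum_k T0 exp(-mu Phi_k) sin(phi_k)``; linear and monotone
    increasing in T0, non-increasing in mu, and equal to the
    frictionless closed form at mu = 0.
    """
    if tension_n < 0:
        raise ValueError("cable tension must be non-negative")
    tensions = g.segment_tensions(tension_n)
    phi = np.deg2rad(g.segment_angles_deg)
    return float(np.sum(tensions * np.sin(phi)))


def frictionless_normal_force(tension_n: float, g: PulleyGeometry) -> float:
    """Closed form ``N = T0 * sum_k sin(phi_k)`` (mu = 0 limit)."""
    phi = np.deg2rad(g.segment_angles_deg)
    return float(tension_n * np.sum(np.sin(phi)))


def geometry_from_coordinates(
    plate_xyz: np.ndarray,
    anchor_xyz: np.ndarray,
    plate_normal: np.ndarray = (0.0, 0.0, 1.0),
    **kwargs,
) -> PulleyGeometry:
    """Build a PulleyGeometry whose anchor angles match explicit coordinates.

    The anchor angle of each anchor is the elevation of the plate->anchor
    line out of the plate plane (the plane through the plate orthogonal
    to ``plate_normal``).
    """
    plate = np.asarray(plate_xyz, dtype=float)
    anchors = np.atleast_2d(np.asarray(anchor_xyz, dtype=float))
    n_hat = np.asarray(plate_normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    vecs = anchors - plate
    lens = np.linalg.norm(vecs, axis=1)
    sin_phi = np.abs(vecs @ n_hat) / lens
    angles = np.degrees(np.arcsin(np.clip(sin_phi, 0, 1)))
    return PulleyGeometry(
        anchor_angles_deg=angles,
        n_segments=2 * len(anchors),
        plate_xyz=plate,
        anchor_xyz=anchors,
        **kwargs,
    )


def equilibrium_oracle(
    g: PulleyGeometry,
    tension_n: float,
    plate_normal: np.ndarray = (0.0, 0.0, 1.0),
    angle_tol_deg: float = 1.0,
) -> float:
    """Normal force from explicit 3D statics; test-only reference path.

    Each segment's tension vector is built from the actual plate->anchor
    unit vector (capstan-attenuated magnitude); the oracle sums the
    components along the plate normal. Raises if the declared anchor
    angles disagree with the coordinates by more than ``angle_tol_deg``.
    """
    if g.plate_xyz is None or g.anchor_xyz is None:
        raise ValueError("equilibrium oracle needs explicit plate/anchor coordinates")
    plate = np.asarray(g.plate_xyz, dtype=float)
    anchors = np.atleast_2d(np.asarray(g.anchor_xyz, dtype=float))
    n_hat = np.asarray(plate_normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    vecs = anchors - plate
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    coord_angles = np.degrees(np.arcsin(np.clip(np.abs(units @ n_hat), 0, 1)))
    if np.any(np.abs(coord_angles - g.anchor_angles_deg) > angle_tol_deg):
        raise ValueError(
            "declared anchor angles inconsistent with coordinates: "
            f"{g.anchor_angles_deg} vs {coord_angles}"
        )
    tensions = g.segment_tensions(tension_n)
    normal_components = np.abs(units @ n_hat)  # per anchor
    per_segment = np.repeat(normal_components, 2)
    return float(np.sum(tensions * per_segment))


def validate_model(
    pairs: Sequence[tuple[float, float]],
) -> dict:
    """Least-squares validation of modelled vs reference normal force.

    Parameters
    ----------
    pairs : sequence of (model prediction, reference normal force) in N.

    Returns
    -------
    dict with slope, intercept, r_squared and a ``negative_slope`` flag
    (anti-correlated data).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (model, reference) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate validation input: constant values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if slope < 0:
        logger.warning("validation fit has negative slope: model anti-correlated")
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": r2,
        "negative_slope": bool(slope < 0),
    }


@dataclass
class PressureCheck:
    pressure_pa: float
    short_term_ok: bool
    long_term_ok: bool
    anterior_demand_ok: bool
    lateral_demand_ok: bool


def check_pressure_limits(
    normal_force_n: float,
    interface_area_m2: float,
    anterior_demand_n: Optional[float] = None,
    lateral_demand_n: Optional[float] = None,
) -> PressureCheck:
    """Skin-pressure and force-demand safety check.

    Pressure = N / area; short-term skin pressure must stay <= 16 kPa,
    long-term <= 4 kPa. Optional modelled force demands are flagged
    against the literature bounds of 100 N (anterior) and 82 N (lateral)
    required to stabilise a winging scapula.
    """
    if interface_area_m2 <= 0:
        raise ValueError("interface area must be positive")
    p = normal_force_n / interface_area_m2
    return PressureCheck(
        pressure_pa=float(p),
        short_term_ok=bool(p <= SHORT_TERM_PRESSURE_LIMIT_PA),
        long_term_ok=bool(p <= LONG_TERM_PRESSURE_LIMIT_PA),
        anterior_demand_ok=bool(
            anterior_demand_n is None or anterior_demand_n <= ANTERIOR_FORCE_BOUND_N
        ),
        lateral_demand_ok=bool(
            lateral_demand_n is None or lateral_demand_n <= LATERAL_FORCE_BOUND_N
        ),
    )
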