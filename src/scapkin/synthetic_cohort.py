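"""Synthetic motion-capture cohort generator.

Emulates the assistance study's recordings so that every downstream
stage (angle reconstruction, segmentation, smoothness, effect models) is
testable without the deposited dataset: 8 participants, 8 study blocks
(unassisted baseline, six orthosis force levels, therapist), 2
repetitions x 2 directions per block (flexion at alpha = 80 deg,
abduction at alpha = 30 deg), bell-shaped elevations with a 5 s hold at
peak, scapulohumeral coupling per configurable ScAla ratios, trunk
compensation proportional to elevation, condition effects on peak
elevation, and millimetre-scale marker noise.

The forward model places the 10 study markers (IJ, PX, C7, T8, both
acromia, humeral epicondyles, radial/ulnar styloids) in the global frame
of :mod:`scapkin.frame`, plus two clearly synthetic scapula medial-border
annotation markers that stand in for the study's reference-picture
scapula annotation (the optical marker set itself never saw the
scapula). Noise-free forward marker sets round-trip through
:mod:`scapkin.kinematics` to better than 0.1 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from scapkin.frame import FORWARD, LEFT, UP
from scapkin.kinematics import GH_OFFSET_MM, AngleSeries
from scapkin.mocap_io import MarkerFrameSeries, TrialMetadata
from scapkin.smoothness import minimum_jerk_trajectory

DirectionMap = Mapping[str, float]

FLEXION_ALPHA_DEG = 80.0
ABDUCTION_ALPHA_DEG = 30.0
N_ORTHOSIS_LEVELS = 6
ROM_BLOCKS = ("none",) + tuple(
    f"orthosis-level-{k}" for k in range(1, N_ORTHOSIS_LEVELS + 1)
) + ("therapist",)

#: movement phase durations (s): rest, minimum-jerk ascent, hold, descent, rest
PHASE_DURATIONS_S = (0.5, 2.0, 5.0, 2.0, 0.5)


def _as_direction_map(value: Union[float, DirectionMap]) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {str(k): float(v) for k, v in value.items()}
        missing = {"flexion", "abduction"} - set(out)
        if missing:
            raise ValueError(f"direction map missing {missing}")
        return out
    return {"flexion": float(value), "abduction": float(value)}


@dataclass
class ParticipantSpec:
    """Anthropometry, pathology and condition-response of one simulated participant.

    ``scala_ratio`` is the scapular rotation per unit glenohumeral
    elevation (0.5 = physiological scapulohumeral rhythm, negative =
    medial winging); ``compensation_slope`` the trunk compensation per
    degree of gravitational elevation. Gains are degrees added to the
    peak corrected elevation, per direction (scalars broadcast to both
    directions); the orthosis curve maps force level 1..6 to its gain.
    """

    id: str
    height: float = 1.75  # m
    upper_arm_length: float = 0.33  # m
    forearm_length: float = 0.26  # m
    shoulder_width: float = 0.40  # m
    baseline_peak_elevation: float = 105.0  # deg, peak corrected elevation
    scala_ratio: float = 0.5
    compensation_slope: float = 0.15  # deg kappa per deg theta_g
    therapist_gain: Union[float, DirectionMap] = 0.0
    orthosis_gain_curve: Mapping[int, Union[float, DirectionMap]] = field(
        default_factory=lambda: {k: 0.0 for k in range(1, N_ORTHOSIS_LEVELS + 1)}
    )
    marker_noise_sd: float = 1.0  # mm
    peak_sd: float = 0.0  # deg, trial-to-trial peak-elevation jitter

    def __post_init__(self) -> None:
        for name in ("height", "upper_arm_length", "forearm_length", "shoulder_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.baseline_peak_elevation < 180:
            raise ValueError("baseline peak elevation must lie in (0, 180) degrees")
        if not 0 <= self.compensation_slope <= 0.5:
            raise ValueError("compensation slope must lie in [0, 0.5]")
        self.therapist_gain = _as_direction_map(self.therapist_gain)
        curve = {int(k): _as_direction_map(v) for k, v in self.orthosis_gain_curve.items()}
        if sorted(curve) != list(range(1, N_ORTHOSIS_LEVELS + 1)):
            raise ValueError("orthosis gain curve must define exactly levels 1..6")
        self.orthosis_gain_curve = curve
        if self.marker_noise_sd < 0 or self.peak_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def condition_gain(self, condition: str, direction: str) -> float:
        """Degrees added to the peak corrected elevation for a condition label."""
        kind, level = parse_condition(condition)
        if kind == "none":
            return 0.0
        if kind == "therapist":
            return self.therapist_gain[direction]
        return self.orthosis_gain_curve[level][direction]


@dataclass
class TrialPlan:
    """Schedule entry for one elevation (one repetition of one direction)."""

    participant: str
    condition: str  # none | orthosis-level-k | therapist
    direction: str  # flexion | abduction
    repetition: int  # 1 or 2
    bottle_mass: float = 0.0  # kg
    duration: float = float(sum(PHASE_DURATIONS_S))  # s
    sample_rate: float = 100.0  # Hz
    seed: int = 0
    block_index: int = 0
    comp_slope_factor: float = 1.0  # condition effect on the compensation slope

    def __post_init__(self) -> None:
        parse_condition(self.condition)
        if self.direction not in ("flexion", "abduction"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.repetition not in (1, 2):
            raise ValueError("repetition must be 1 or 2")
        if self.bottle_mass not in (0.0, 0.25, 0.50):
            raise ValueError("bottle mass must be 0, 0.25 or 0.50 kg")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("duration and sample rate must be positive")

    @property
    def alpha_deg(self) -> float:
        return FLEXION_ALPHA_DEG if self.direction == "flexion" else ABDUCTION_ALPHA_DEG

    def metadata(self) -> TrialMetadata:
        kind, level = parse_condition(self.condition)
        return TrialMetadata(
            participant=self.participant,
            condition=kind,
            direction=self.direction,
            repetition=self.repetition,
            block_index=self.block_index,
            force_level=level,
            bottle_mass=self.bottle_mass,
        )


def parse_condition(condition: str) -> tuple[str, Optional[int]]:
    """Split a condition label into (kind, orthosis force level or None)."""
    if condition in ("none", "therapist"):
        return condition, None
    if condition.startswith("orthosis-level-"):
        try:
            level = int(condition.rsplit("-", 1)[1])
        except ValueError:
            level = -1
        if 1 <= level <= N_ORTHOSIS_LEVELS:
            return "orthosis", level
    raise ValueError(f"unknown condition label {condition!r}")


@dataclass
class SimulatedTrial:
    """Marker series plus ground-truth angles for one scheduled elevation."""

    plan: TrialPlan
    markers: MarkerFrameSeries
    truth: AngleSeries

    @property
    def metadata(self) -> TrialMetadata:
        return self.plan.metadata()


# ---------------------------------------------------------------------------
# forward kinematic marker model


def _plane_direction(alpha_deg: np.ndarray) -> np.ndarray:
    """Horizontal reach direction u for plane-of-elevation angle alpha.

    alpha = 0 points sideward along the acromion line (right side for the
    instrumented arm), alpha = 90 straight forward.
    """
    a = np.deg2rad(np.atleast_1d(alpha_deg))
    return np.outer(np.sin(a), FORWARD) - np.outer(np.cos(a), LEFT)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rotate per-frame vectors v (n,3) about per-frame unit axes by angles."""
    c = np.cos(angle_rad)[:, None]
    s = np.sin(angle_rad)[:, None]
    dot = np.sum(axis * v, axis=1, keepdims=True)
    return v * c + np.cross(axis, v) * s + axis * dot * (1 - c)


def forward_markers(
    theta_gh: np.ndarray,
    rho: np.ndarray,
    kappa: np.ndarray,
    alpha: np.ndarray,
    p: ParticipantSpec,
    times: Optional[np.ndarray] = None,
    sample_rate: float = 100.0,
    include_scapula: bool = True,
) -> MarkerFrameSeries:
    """Noise-free marker positions for a per-frame pose.

    The pose is (theta_gh, rho, kappa, alpha) in degrees;
    theta_g = theta_gh + rho. The thorax (with both acromia) is tilted
    by kappa within the plane of elevation about a lumbar pivot, the
    straight arm leaves the glenohumeral point at theta_g from vertical
    within the same plane, and the synthetic scapula medial-border
    markers encode rho against gravity. All angles must be finite and
    the same length as the time base.
    """
    pose = [np.atleast_1d(np.asarray(a, dtype=float)) for a in (theta_gh, rho, kappa, alpha)]
    n = len(pose[0])
    if any(len(a) != n for a in pose):
        raise ValueError("pose angle series have mismatched lengths")
    if times is None:
        times = np.arange(n) / sample_rate
    elif len(times) != n:
        raise ValueError("pose length mismatch with time base")
    if not all(np.all(np.isfinite(a)) for a in pose):
        raise ValueError("pose angles must be finite")
    theta_gh_a, rho_a, kappa_a, alpha_a = pose
    theta_g = theta_gh_a + rho_a

    s = p.height / 1.75
    w = p.shoulder_width * 1000.0
    thorax0 = {
        "IJ": np.array([80.0 * s, 0.0, -50.0 * s]),
        "PX": np.array([90.0 * s, 0.0, -280.0 * s]),
        "C7": np.array([-80.0 * s, 0.0, -50.0 * s]),
        "T8": np.array([-90.0 * s, 0.0, -280.0 * s]),
        "RACR": np.array([0.0, -w / 2.0, 0.0]),
        "LACR": np.array([0.0, w / 2.0, 0.0]),
    }
    scap0 = np.array([-70.0 * s, -w / 2.0 + 15.0, -20.0])
    pivot = np.array([0.0, 0.0, -400.0 * s])

    u = _plane_direction(alpha_a)  # (n,3)
    tilt_axis = np.cross(u, UP[None, :])  # unit: u and UP orthonormal
    kappa_rad = np.deg2rad(kappa_a)

    markers: dict[str, np.ndarray] = {}
    for name, point in thorax0.items():
        rel = np.broadcast_to(point - pivot, (n, 3))
        markers[name] = pivot + _rodrigues(rel, tilt_axis, kappa_rad)

    sternum_axis = _rodrigues(np.broadcast_to(UP, (n, 3)), tilt_axis, kappa_rad)
    gh = markers["RACR"] - GH_OFFSET_MM * sternum_axis

    tg = np.deg2rad(theta_g)
    arm_dir = np.sin(tg)[:, None] * u - np.cos(tg)[:, None] * UP
    arm_mm = (p.upper_arm_length + p.forearm_length) * 1000.0
    elbow = gh + p.upper_arm_length * 1000.0 * arm_dir
    wrist = gh + arm_mm * arm_dir

    lat = np.cross(arm_dir, np.broadcast_to(FORWARD, (n, 3)))
    small = np.linalg.norm(lat, axis=1) < 1e-6
    if np.any(small):
        lat[small] = np.cross(arm_dir[small], LEFT[None, :])
    lat /= np.linalg.norm(lat, axis=1, keepdims=True)
    markers["RLE"] = elbow + 30.0 * lat
    markers["RME"] = elbow - 30.0 * lat
    markers["RRS"] = wrist + 25.0 * lat
    markers["RUS"] = wrist - 25.0 * lat

    if include_scapula:
        rel = np.broadcast_to(scap0 - pivot, (n, 3))
        sup = pivot + _rodrigues(rel, tilt_axis, kappa_rad)
        rr = np.deg2rad(rho_a)
        border = np.sin(rr)[:, None] * u - np.cos(rr)[:, None] * UP
        markers["RSCAP_SUP"] = sup
        markers["RSCAP_INF"] = sup + 120.0 * border

    order = ["IJ", "PX", "C7", "T8", "RACR", "LACR", "RLE", "RME", "RRS", "RUS"]
    if include_scapula:
        order += ["RSCAP_SUP", "RSCAP_INF"]
    return MarkerFrameSeries(
        sample_rate=sample_rate,
        times=np.asarray(times, dtype=float),
        markers={name: markers[name] for name in order},
    )


# ---------------------------------------------------------------------------
# trial simulation


def elevation_profile(
    peak_theta: float,
    sample_rate: float,
    phases: Sequence[float] = PHASE_DURATIONS_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected-elevation time course: rest, minimum-jerk ascent,
    hold at peak, minimum-jerk descent, rest. Returns (times, theta)."""
    rest0, t_up, t_hold, t_down, rest1 = phases
    rate = sample_rate
    _, up, _ = minimum_jerk_trajectory(peak_theta, t_up, rate)
    theta = np.concatenate(
        [
            np.zeros(int(round(rest0 * rate))),
            up,
            np.full(int(round(t_hold * rate)) - 1, peak_theta),
            peak_theta - up[1:],
            np.zeros(int(round(rest1 * rate))),
        ]
    )
    times = np.arange(len(theta)) / rate
    return times, theta


def simulate_trial(p: ParticipantSpec, plan: TrialPlan) -> SimulatedTrial:
    """Simulate one scheduled elevation: markers plus ground-truth angles.

    The corrected elevation theta follows a minimum-jerk ascent to the
    condition-adjusted peak, a >= 5 s hold and a minimum-jerk descent.
    Trunk compensation is proportional to the gravitational elevation
    (kappa = c * theta_g with c the participant's slope scaled by the
    condition factor), scapular rotation follows the ScAla coupling
    (rho = x/(1+x) * theta_g), and markers carry isotropic Gaussian
    noise of the participant's magnitude. Identical seeds reproduce the
    trial bit for bit.
    """
    if plan.participant != p.id:
        raise ValueError("trial plan does not reference this participant")
    rng = np.random.default_rng(plan.seed)

    peak = p.baseline_peak_elevation + p.condition_gain(plan.condition, plan.direction)
    if peak <= 0:
        raise ValueError("condition adjustment drove the peak elevation non-positive")
    if p.peak_sd > 0:
        peak = max(peak + rng.normal(0.0, p.peak_sd), 1.0)

    times, theta = elevation_profile(peak, plan.sample_rate)
    c = p.compensation_slope * plan.comp_slope_factor
    if not 0 <= c < 1:
        raise ValueError("effective compensation slope must lie in [0, 1)")
    theta_g = theta / (1.0 - c)
    if theta_g.max() >= 179.0:
        raise ValueError(
            "pose exceeds the 180 deg gravitational-elevation range; "
            "peak elevation and compensation slope are jointly too large"
        )
    kappa = c * theta_g
    x = p.scala_ratio
    rho = x / (1.0 + x) * theta_g
    theta_gh = theta_g - rho
    alpha = np.full_like(theta_g, plan.alpha_deg)

    markers = forward_markers(
        theta_gh, rho, kappa, alpha, p, times=times, sample_rate=plan.sample_rate
    )
    if p.marker_noise_sd > 0:
        for name in markers.marker_names:
            markers.markers[name] = markers.markers[name] + rng.normal(
                0.0, p.marker_noise_sd, size=markers.markers[name].shape
            )

    truth = AngleSeries(
        times=times,
        sample_rate=plan.sample_rate,
        theta_g=theta_g,
        kappa=kappa,
        theta=theta,
        alpha=alpha,
        rho=rho,
        theta_gh=theta_gh,
    )
    return SimulatedTrial(plan=plan, markers=markers, truth=truth)


# ---------------------------------------------------------------------------
# cohort construction


@dataclass
class EffectProfile:
    """Population-level condition effects the generator reproduces.

    Defaults are the study conditions: mean therapist gains of 17.3 deg
    (flexion) / 11.2 deg (abduction) and mean maximal-orthosis gains of
    6.2 / 5.8 deg with between-participant spreads matched to the
    reported confidence intervals; trunk-compensation slope reductions
    of 13.0% / 23.8% (therapist) and 8.6% / 15.1% (orthosis); baseline
    ScAla ratios spanning the observed 0.2 .. -0.4 range.
    """

    therapist_gain_mean: DirectionMap = field(
        default_factory=lambda: {"flexion": 17.3, "abduction": 11.2}
    )
    therapist_gain_sd: DirectionMap = field(
        default_factory=lambda: {"flexion": 10.9, "abduction": 9.4}
    )
    orthosis_max_gain_mean: DirectionMap = field(
        default_factory=lambda: {"flexion": 6.2, "abduction": 5.8}
    )
    orthosis_max_gain_sd: DirectionMap = field(
        default_factory=lambda: {"flexion": 8.3, "abduction": 4.0}
    )
    therapist_slope_factor: DirectionMap = field(
        default_factory=lambda: {"flexion": 1 - 0.130, "abduction": 1 - 0.238}
    )
    orthosis_slope_factor: DirectionMap = field(
        default_factory=lambda: {"flexion": 1 - 0.086, "abduction": 1 - 0.151}
    )
    baseline_peak_range: tuple[float, float] = (85.0, 125.0)
    scala_ratio_range: tuple[float, float] = (-0.4, 0.2)
    compensation_slope_range: tuple[float, float] = (0.04, 0.37)
    height_range: tuple[float, float] = (1.58, 1.89)
    marker_noise_sd: float = 1.0
    peak_sd: float = 1.5

    def slope_factor(self, condition: str, direction: str) -> float:
        kind, _ = parse_condition(condition)
        if kind == "therapist":
            return self.therapist_slope_factor[direction]
        if kind == "orthosis":
            return self.orthosis_slope_factor[direction]
        return 1.0


@dataclass
class Cohort:
    participants: list[ParticipantSpec]
    plans: list[TrialPlan]
    profile: EffectProfile
    seed: int

    def schedule_records(self) -> list[dict]:
        """Serializable schedule: one dict per planned elevation."""
        return [
            {
                "participant": pl.participant,
                "block_index": pl.block_index,
                "condition": pl.condition,
                "direction": pl.direction,
                "repetition": pl.repetition,
                "bottle_mass": pl.bottle_mass,
                "seed": pl.seed,
            }
            for pl in self.plans
        ]


def _draw_participant(
    pid: str, profile: EffectProfile, rng: np.random.Generator
) -> ParticipantSpec:
    height = rng.uniform(*profile.height_range)
    baseline = rng.uniform(*profile.baseline_peak_range)
    # corrected-elevation peaks cap at ~160 deg (near the passive limit)
    gain_cap = 160.0 - baseline - 5 * profile.peak_sd
    ther = {
        d: min(rng.normal(profile.therapist_gain_mean[d], profile.therapist_gain_sd[d]), gain_cap)
        for d in ("flexion", "abduction")
    }
    orth_max = {
        d: min(
            rng.normal(profile.orthosis_max_gain_mean[d], profile.orthosis_max_gain_sd[d]),
            gain_cap,
        )
        for d in ("flexion", "abduction")
    }
    curve = {
        k: {d: orth_max[d] * k / N_ORTHOSIS_LEVELS for d in ("flexion", "abduction")}
        for k in range(1, N_ORTHOSIS_LEVELS + 1)
    }
    # compensation slope is bounded jointly with the peak so that the
    # gravitational elevation theta/(1-c) stays below the physical 180 deg
    # (steep compensators in the study were also the lower elevators)
    theta_max = baseline + max(0.0, *ther.values(), *orth_max.values()) + 5 * profile.peak_sd
    c_lo = profile.compensation_slope_range[0]
    c_hi = max(c_lo, min(profile.compensation_slope_range[1], 1.0 - theta_max / 172.0))
    return ParticipantSpec(
        id=pid,
        height=height,
        upper_arm_length=0.186 * height,
        forearm_length=0.146 * height,
        shoulder_width=0.23 * height,
        baseline_peak_elevation=baseline,
        scala_ratio=rng.uniform(*profile.scala_ratio_range),
        compensation_slope=rng.uniform(c_lo, c_hi),
        therapist_gain=ther,
        orthosis_gain_curve=curve,
        marker_noise_sd=profile.marker_noise_sd,
        peak_sd=profile.peak_sd,
    )


def make_cohort(
    n_participants: int = 8,
    profile: Optional[EffectProfile] = None,
    seed: int = 0,
) -> Cohort:
    """Draw a cohort and its full randomized crossover block schedule.

    Each participant performs 8 blocks (baseline, six orthosis force
    levels, therapist) in randomized order; within each block, two
    elevations per direction in randomized direction order. Identical
    seeds give identical cohorts and schedules.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    profile = profile or EffectProfile()
    rng = np.random.default_rng(seed)
    participants = [
        _draw_participant(f"P{i + 1}", profile, rng) for i in range(n_participants)
    ]
    plans: list[TrialPlan] = []
    for p in participants:
        blocks = list(ROM_BLOCKS)
        rng.shuffle(blocks)
        for bi, condition in enumerate(blocks):
            directions = ["flexion", "abduction"]
            rng.shuffle(directions)
            for direction in directions:
                for rep in (1, 2):
                    plans.append(
                        TrialPlan(
                            participant=p.id,
                            condition=condition,
                            direction=direction,
                            repetition=rep,
                            seed=int(rng.integers(2**31)),
                            block_index=bi,
                            comp_slope_factor=profile.slope_factor(condition, direction),
                        )
                    )
    return Cohort(participants=participants, plans=plans, profile=profile, seed=seed)
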