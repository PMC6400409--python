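"""Synthetic screw-joint experiment generator with exact ground truth.

Emulates an in-vitro elbow flexion experiment: a flexion gesture of the
radius-ulna against a fixed humerus (0-91 degrees over 40 s at 100 Hz),
tracked by two rigid four-marker clusters with isotropic Gaussian marker
noise (sigma = 0.012 mm, the DIC measurement uncertainty), and
bone-surface patches (humeral head sphere cap, humeral trochlea
cylinder, distal-radius carpal trochlea cylinder) digitized with scanner
noise (sigma = 0.02 mm).  The joint is a screw joint: rotation about a
fixed axis coupled with a flexion-dependent medial-lateral translation.

Two named scenarios reproduce the study conditions:

* ``fresh`` — intact joint: smooth monotone medial-lateral translation
  from 0.002 mm at 0 degrees to 0.457 mm at 91 degrees; all other
  non-flexion DoFs zero.
* ``dry`` — bones without soft tissue: reduced flexion range
  (0-70 degrees), a non-monotone medial-lateral translation spanning
  -0.81 to -0.017 mm, and small adduction-abduction / internal-external
  perturbations (tens of millidegrees).

Every generated quantity is paired with the exact planted value, so each
downstream stage is testable by parameter recovery.  Generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (
    ClusterGeometry,
    InvalidScenarioError,
    MarkerTrajectorySet,
    PoseSeries,
    rotation_about_axis,
    unit,
)
from .frames import Landmarks

__all__ = [
    "GroundTruth",
    "SpherePatchSpec",
    "CylinderPatchSpec",
    "SyntheticBoneSet",
    "smoothstep",
    "make_screw_motion",
    "make_marker_trajectories",
    "make_bone_geometry",
    "make_scenario",
    "make_study",
    "default_cluster_geometries",
    "default_landmarks",
    "SCENARIOS",
]

Profile = Callable[[np.ndarray], np.ndarray]


def smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp 3x^2 - 2x^3 clipped to [0, 1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _perp_pair(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(u, helper))
    return e1, np.cross(u, e1)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Planted scenario: joint axis, motion profiles and noise levels.

    ``angle_profile`` maps time (s) to flexion angle (degrees), monotone
    non-decreasing; ``axial_translation_profile`` maps flexion angle
    (degrees) to medial-lateral translation (mm).  Optional perturbation
    profiles (functions of flexion angle) add the small non-screw DoFs of
    the dry scenario.  ``body_origin``/``body_rotation`` give the moving
    bone's reference (unloaded, zero-flexion) pose, which is also the
    displacement reference for recovery comparisons.
    """

    axis_point: np.ndarray  # mm
    axis_direction: np.ndarray  # unit
    angle_profile: Profile  # t [s] -> flexion [deg]
    axial_translation_profile: Profile  # flexion [deg] -> T_Z [mm]
    marker_noise_sigma: float = 0.012  # mm
    surface_noise_sigma: float = 0.02  # mm
    dt: float = 0.01  # s
    duration: float = 40.0  # s
    seed: int = 0
    name: str = "custom"
    rx_profile: Profile | None = None  # flexion [deg] -> R_X [deg]
    ry_profile: Profile | None = None  # flexion [deg] -> R_Y [deg]
    tx_profile: Profile | None = None  # flexion [deg] -> T_X [mm]
    ty_profile: Profile | None = None  # flexion [deg] -> T_Y [mm]
    body_origin: np.ndarray = field(default_factory=lambda: np.array([25.0, -40.0, 8.0]))
    body_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_origin: np.ndarray | None = None  # joint-frame origin on the axis
    frame_rotation: np.ndarray | None = None  # columns (U_X, U_Y, U_Z)
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-12:
            raise InvalidScenarioError("axis_direction must have unit norm")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidScenarioError("dt and duration must be positive")
        if self.marker_noise_sigma < 0 or self.surface_noise_sigma < 0:
            raise InvalidScenarioError("noise sigmas must be non-negative")
        theta = np.asarray(self.angle_profile(self.times), dtype=float)
        if np.any(np.diff(theta) < -1e-9):
            raise InvalidScenarioError("angle_profile must be monotone non-decreasing")
        if self.frame_rotation is None:
            u = self.axis_direction
            e1, e2 = _perp_pair(u)
            self.frame_rotation = np.column_stack([e1, e2, u])
        if self.frame_origin is None:
            self.frame_origin = self.axis_point.copy()
        self.frame_origin = np.asarray(self.frame_origin, dtype=float)
        self.frame_rotation = np.asarray(self.frame_rotation, dtype=float)
        self.body_origin = np.asarray(self.body_origin, dtype=float)
        self.body_rotation = np.asarray(self.body_rotation, dtype=float)

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    @property
    def reference_pose(self) -> tuple[np.ndarray, np.ndarray]:
        """Unloaded zero-flexion pose (rotation, origin) of the moving bone."""
        return self.body_rotation.copy(), self.body_origin.copy()

    @property
    def flexion_range(self) -> tuple[float, float]:
        theta = self.angle_profile(self.times)
        return float(np.min(theta)), float(np.max(theta))

    def planted_dof_profiles(self, flexion_deg: np.ndarray) -> dict[str, np.ndarray]:
        """All six planted DoF values on a flexion grid (deg / mm)."""
        f = np.asarray(flexion_deg, dtype=float)
        zero = np.zeros_like(f)
        return {
            "R_Z": f.copy(),
            "R_Y": self.ry_profile(f) if self.ry_profile else zero.copy(),
            "R_X": self.rx_profile(f) if self.rx_profile else zero.copy(),
            "T_X": self.tx_profile(f) if self.tx_profile else zero.copy(),
            "T_Y": self.ty_profile(f) if self.ty_profile else zero.copy(),
            "T_Z": np.asarray(self.axial_translation_profile(f), dtype=float),
        }


# ---------------------------------------------------------------------------
# motion and markers


def make_screw_motion(truth: GroundTruth) -> PoseSeries:
    """Forward model: pose series of the planted joint motion.

    In the planted joint frame the displacement at flexion theta is the
    Tait-Bryan cascade Rot_Z(theta) Rot_Y(ry) Rot_X(rx) plus the
    translation (tx, ty, tz); for a pure screw (all perturbations zero)
    this is exactly a rotation about the fixed axis with a translation
    along it.
    """
    t = truth.times
    theta = np.radians(np.asarray(truth.angle_profile(t), dtype=float))
    theta_deg = np.degrees(theta)
    tz = np.asarray(truth.axial_translation_profile(theta_deg), dtype=float)
    zero = np.zeros_like(theta)
    rx = np.radians(truth.rx_profile(theta_deg)) if truth.rx_profile else zero
    ry = np.radians(truth.ry_profile(theta_deg)) if truth.ry_profile else zero
    tx = truth.tx_profile(theta_deg) if truth.tx_profile else zero
    ty = truth.ty_profile(theta_deg) if truth.ty_profile else zero

    cz, sz = np.cos(theta), np.sin(theta)
    cy, sy = np.cos(ry), np.sin(ry)
    cx, sx = np.cos(rx), np.sin(rx)
    n = t.size
    D = np.empty((n, 3, 3))
    D[:, 0, 0] = cz * cy
    D[:, 0, 1] = cz * sy * sx - sz * cx
    D[:, 0, 2] = cz * sy * cx + sz * sx
    D[:, 1, 0] = sz * cy
    D[:, 1, 1] = sz * sy * sx + cz * cx
    D[:, 1, 2] = sz * sy * cx - cz * sx
    D[:, 2, 0] = -sy
    D[:, 2, 1] = cy * sx
    D[:, 2, 2] = cy * cx

    Q = truth.frame_rotation
    Ob = truth.frame_origin
    R0, O0 = truth.reference_pose
    Rd = np.einsum("ij,njk,lk->nil", Q, D, Q)
    R = np.einsum("nij,jk->nik", Rd, R0)
    trans = np.column_stack([tx, ty, tz])
    O = np.einsum("nij,j->ni", Rd, O0 - Ob) + Ob + np.einsum("ij,nj->ni", Q, trans)
    return PoseSeries(times=t, rotations=R, origins=O)


def make_marker_trajectories(
    poses: PoseSeries,
    geom_fixed: ClusterGeometry,
    geom_moving: ClusterGeometry,
    sigma: float,
    seed: int,
) -> MarkerTrajectorySet:
    """Noisy lab-frame marker trajectories for both tracking clusters.

    Fixed-cluster markers sit at their body-frame offsets (the lab frame
    coincides with the fixed bone frame); moving-cluster markers follow
    the pose series.  Both receive i.i.d. isotropic Gaussian noise of
    standard deviation ``sigma`` per coordinate.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n = poses.n_frames
    fixed_clean = np.broadcast_to(
        geom_fixed.marker_offsets[None, :, :], (n, geom_fixed.n_markers, 3)
    ).copy()
    moving_clean = poses.transform_points(geom_moving.marker_offsets)
    fixed = fixed_clean + rng.normal(0.0, sigma, fixed_clean.shape) if sigma else fixed_clean
    moving = (
        moving_clean + rng.normal(0.0, sigma, moving_clean.shape) if sigma else moving_clean
    )
    clusters = {
        "fixed": {
            name: fixed[:, i, :] for i, name in enumerate(geom_fixed.marker_names)
        },
        "moving": {
            name: moving[:, i, :] for i, name in enumerate(geom_moving.marker_names)
        },
    }
    return MarkerTrajectorySet(times=poses.times.copy(), clusters=clusters)


# ---------------------------------------------------------------------------
# bone geometry


@dataclass(frozen=True)
class SpherePatchSpec:
    center: np.ndarray
    radius: float
    cap_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    cap_angle_deg: float = 70.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "cap_direction", unit(self.cap_direction))
        if self.radius <= 0:
            raise InvalidScenarioError("sphere radius must be positive")


@dataclass(frozen=True)
class CylinderPatchSpec:
    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    arc_extent_deg: float = 120.0
    arc_start_deg: float = 0.0
    length: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        object.__setattr__(self, "axis_direction", unit(self.axis_direction))
        if self.radius <= 0 or self.length <= 0:
            raise InvalidScenarioError("cylinder radius and length must be positive")


@dataclass
class SyntheticBoneSet:
    """Labelled noisy surface point clouds, landmarks and their planted truth."""

    regions: dict[str, np.ndarray]
    landmarks: Landmarks  # digitized (noisy)
    true_landmarks: Landmarks
    true_sphere: SpherePatchSpec
    true_humeral_cylinder: CylinderPatchSpec
    true_radial_cylinder: CylinderPatchSpec
    degenerate_extent: dict[str, bool] = field(default_factory=dict)


def _sample_sphere_cap(spec: SpherePatchSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    cosmax = np.cos(np.radians(spec.cap_angle_deg))
    z = rng.uniform(cosmax, 1.0, n)
    az = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    local = np.column_stack([s * np.cos(az), s * np.sin(az), z])
    e1, e2 = _perp_pair(spec.cap_direction)
    M = np.column_stack([e1, e2, spec.cap_direction])
    return spec.center + spec.radius * local @ M.T


def _sample_cylinder_patch(
    spec: CylinderPatchSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    a0 = np.radians(spec.arc_start_deg)
    ext = np.radians(spec.arc_extent_deg)
    ang = rng.uniform(a0, a0 + ext, n)
    h = rng.uniform(-spec.length / 2.0, spec.length / 2.0, n)
    e1, e2 = _perp_pair(spec.axis_direction)
    return (
        spec.axis_point
        + spec.radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
        + h[:, None] * spec.axis_direction
    )


def make_bone_geometry(
    truth: GroundTruth,
    sphere: SpherePatchSpec,
    humeral_cylinder: CylinderPatchSpec,
    radial_cylinder: CylinderPatchSpec,
    landmarks: Landmarks,
    n_points: int = 2000,
    seed: int = 0,
) -> SyntheticBoneSet:
    """Noisy labelled surface patches plus landmark points.

    Each surface point and landmark receives isotropic Gaussian noise of
    std ``truth.surface_noise_sigma`` per coordinate.  Patches subtending
    less than 30 degrees of arc are flagged as degenerate in the output.
    """
    if n_points < 50:
        raise InvalidScenarioError("need >= 50 points per surface patch")
    rng = np.random.default_rng(seed)
    sig = truth.surface_noise_sigma

    def noisy(pts: np.ndarray) -> np.ndarray:
        return pts + rng.normal(0.0, sig, pts.shape) if sig else pts

    regions = {
        "humeral_head": noisy(_sample_sphere_cap(sphere, n_points, rng)),
        "humeral_trochlea": noisy(_sample_cylinder_patch(humeral_cylinder, n_points, rng)),
        "radial_trochlea": noisy(_sample_cylinder_patch(radial_cylinder, n_points, rng)),
    }
    noisy_landmarks = Landmarks(
        E_M=landmarks.E_M + rng.normal(0.0, sig, 3),
        E_L=landmarks.E_L + rng.normal(0.0, sig, 3),
        S_r=landmarks.S_r + rng.normal(0.0, sig, 3),
        S_u=landmarks.S_u + rng.normal(0.0, sig, 3),
    )
    flags = {
        "humeral_trochlea": humeral_cylinder.arc_extent_deg < 30.0,
        "radial_trochlea": radial_cylinder.arc_extent_deg < 30.0,
    }
    return SyntheticBoneSet(
        regions=regions,
        landmarks=noisy_landmarks,
        true_landmarks=landmarks,
        true_sphere=sphere,
        true_humeral_cylinder=humeral_cylinder,
        true_radial_cylinder=radial_cylinder,
        degenerate_extent=flags,
    )


# ---------------------------------------------------------------------------
# named scenarios

SCENARIOS = ("fresh", "dry")

# anatomy-scale default layout, mm, humerus frame: +y proximal along the
# humerus, the flexion axis roughly medial-lateral (+z medial, right limb)
AXIS_DIRECTION = unit(np.array([0.08, -0.06, 1.0]))
AXIS_POINT = np.zeros(3)
SPHERE_CENTER = np.array([6.0, 95.0, 4.0])
SPHERE_RADIUS = 16.0
EPICONDYLE_M = np.array([3.0, 2.0, 24.0])
EPICONDYLE_L = np.array([-2.0, -3.0, -22.0])
STYLOID_R = np.array([10.0, -176.0, 9.0])
STYLOID_U = np.array([-8.0, -179.0, -7.0])
RADIAL_TROCHLEA_POINT = np.array([1.0, -176.0, 0.0])
HUMERAL_TROCHLEA_RADIUS = 12.0
RADIAL_TROCHLEA_RADIUS = 11.0
TROCHLEA_OFFSET_AZIMUTH_DEG = 30.0


def default_cluster_geometries() -> tuple[ClusterGeometry, ClusterGeometry]:
    """Two rigid four-marker tracking clusters (fixed bone, moving bone).

    Tetrahedral layouts with ~28 mm RMS marker radius; fixed-cluster
    offsets are lab positions on the humerus shaft, moving-cluster
    offsets are body-frame positions around the radius-ulna cluster
    origin.
    """
    tetra = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / np.sqrt(3.0)
    fixed = ClusterGeometry(
        marker_offsets=np.array([-20.0, 55.0, 5.0]) + 28.0 * tetra,
        marker_names=("h1", "h2", "h3", "h4"),
    )
    moving = ClusterGeometry(
        marker_offsets=28.0 * tetra,
        marker_names=("r1", "r2", "r3", "r4"),
    )
    return fixed, moving


def default_landmarks() -> Landmarks:
    return Landmarks(E_M=EPICONDYLE_M, E_L=EPICONDYLE_L, S_r=STYLOID_R, S_u=STYLOID_U)


def _planted_joint_frame() -> tuple[np.ndarray, np.ndarray]:
    """Joint frame the analysis pipeline will recover, from planted geometry.

    U_Z is the planted axis (oriented medially), U_X the normalized cross
    product of (C_S - axis point) with U_Z, and the origin the projection
    of the epicondyle midpoint onto the axis — the same construction the
    anatomical-frame stage applies to recovered quantities.
    """
    u = AXIS_DIRECTION
    U_X = unit(np.cross(SPHERE_CENTER - AXIS_POINT, u))
    U_Y = np.cross(u, U_X)
    E = 0.5 * (EPICONDYLE_M + EPICONDYLE_L)
    origin = AXIS_POINT + ((E - AXIS_POINT) @ u) * u
    return np.column_stack([U_X, U_Y, u]), origin


def _trochlea_cylinders(
    offset_mm: float, tilt_deg: float
) -> tuple[CylinderPatchSpec, CylinderPatchSpec]:
    """Humeral and radial trochlea patches; the humeral axis is planted at a
    known in-plane offset and tilt from the true flexion axis."""
    Q, origin = _planted_joint_frame()
    U_X, U_Y, u = Q[:, 0], Q[:, 1], Q[:, 2]
    az = np.radians(TROCHLEA_OFFSET_AZIMUTH_DEG)
    w = np.cos(az) * U_X + np.sin(az) * U_Y  # in-plane offset direction
    v = -np.sin(az) * U_X + np.cos(az) * U_Y  # in-plane tilt direction
    p_star = origin + offset_mm * w
    direction = unit(np.cos(np.radians(tilt_deg)) * u + np.sin(np.radians(tilt_deg)) * v)
    humeral = CylinderPatchSpec(
        axis_point=p_star,
        axis_direction=direction,
        radius=HUMERAL_TROCHLEA_RADIUS,
        arc_extent_deg=140.0,
        arc_start_deg=190.0,
        length=25.0,
    )
    radial = CylinderPatchSpec(
        axis_point=RADIAL_TROCHLEA_POINT,
        axis_direction=AXIS_DIRECTION,
        radius=RADIAL_TROCHLEA_RADIUS,
        arc_extent_deg=120.0,
        arc_start_deg=150.0,
        length=20.0,
    )
    return humeral, radial


def _fresh_truth(seed: int, marker_noise_sigma: float, surface_noise_sigma: float) -> GroundTruth:
    Q, origin = _planted_joint_frame()

    def angle(t: np.ndarray) -> np.ndarray:
        return 91.0 * smoothstep(np.asarray(t, dtype=float) / 40.0)

    def tz(f: np.ndarray) -> np.ndarray:
        return 0.002 + (0.457 - 0.002) * smoothstep(np.asarray(f, dtype=float) / 91.0)

    return GroundTruth(
        axis_point=AXIS_POINT,
        axis_direction=AXIS_DIRECTION,
        angle_profile=angle,
        axial_translation_profile=tz,
        marker_noise_sigma=marker_noise_sigma,
        surface_noise_sigma=surface_noise_sigma,
        seed=seed,
        name="fresh",
        frame_rotation=Q,
        frame_origin=origin,
        planted={"trochlea_offset_mm": 1.31, "trochlea_tilt_deg": 5.11},
    )


def _dry_truth(seed: int, marker_noise_sigma: float, surface_noise_sigma: float) -> GroundTruth:
    Q, origin = _planted_joint_frame()
    max_flexion = 70.0  # reduced range without capsule and ligaments
    tz_knots = PchipInterpolator(
        np.array([0.0, 25.0, 50.0, 70.0]),
        np.array([-0.017, -0.30, -0.81, -0.45]),
    )

    def angle(t: np.ndarray) -> np.ndarray:
        return max_flexion * smoothstep(np.asarray(t, dtype=float) / 40.0)

    def tz(f: np.ndarray) -> np.ndarray:
        return tz_knots(np.clip(np.asarray(f, dtype=float), 0.0, max_flexion))

    def rx(f: np.ndarray) -> np.ndarray:
        return 47.5e-3 * np.sin(np.pi * np.asarray(f, dtype=float) / max_flexion)

    def ry(f: np.ndarray) -> np.ndarray:
        return -2.75e-3 + (19.6e-3 + 2.75e-3) * smoothstep(
            np.asarray(f, dtype=float) / max_flexion
        )

    return GroundTruth(
        axis_point=AXIS_POINT,
        axis_direction=AXIS_DIRECTION,
        angle_profile=angle,
        axial_translation_profile=tz,
        marker_noise_sigma=marker_noise_sigma,
        surface_noise_sigma=surface_noise_sigma,
        seed=seed,
        name="dry",
        rx_profile=rx,
        ry_profile=ry,
        frame_rotation=Q,
        frame_origin=origin,
        planted={"trochlea_offset_mm": 1.31, "trochlea_tilt_deg": 5.11},
    )


def make_scenario(
    name: str,
    seed: int,
    *,
    marker_noise_sigma: float = 0.012,
    surface_noise_sigma: float = 0.02,
    n_surface_points: int = 2000,
) -> tuple[MarkerTrajectorySet, SyntheticBoneSet, GroundTruth]:
    """One named trial: marker trajectories, bone set and ground truth."""
    truth = _scenario_truth(name, seed, marker_noise_sigma, surface_noise_sigma)
    poses = make_screw_motion(truth)
    geom_fixed, geom_moving = default_cluster_geometries()
    seeds = np.random.SeedSequence(seed).generate_state(2)
    markers = make_marker_trajectories(
        poses, geom_fixed, geom_moving, marker_noise_sigma, int(seeds[0] % 2**31)
    )
    humeral_cyl, radial_cyl = _trochlea_cylinders(
        truth.planted["trochlea_offset_mm"], truth.planted["trochlea_tilt_deg"]
    )
    sphere = SpherePatchSpec(center=SPHERE_CENTER, radius=SPHERE_RADIUS)
    bones = make_bone_geometry(
        truth,
        sphere,
        humeral_cyl,
        radial_cyl,
        default_landmarks(),
        n_points=n_surface_points,
        seed=int(seeds[1] % 2**31),
    )
    return markers, bones, truth


def _scenario_truth(
    name: str, seed: int, marker_noise_sigma: float, surface_noise_sigma: float
) -> GroundTruth:
    if name == "fresh":
        return _fresh_truth(seed, marker_noise_sigma, surface_noise_sigma)
    if name == "dry":
        return _dry_truth(seed, marker_noise_sigma, surface_noise_sigma)
    raise InvalidScenarioError(
        f"unknown scenario {name!r}; supported scenarios: {', '.join(SCENARIOS)}"
    )


def make_study(
    name: str,
    seed: int,
    n_trials: int = 25,
    *,
    marker_noise_sigma: float = 0.012,
    surface_noise_sigma: float = 0.02,
    n_surface_points: int = 2000,
) -> tuple[list[MarkerTrajectorySet], SyntheticBoneSet, GroundTruth]:
    """A full study: ``n_trials`` repeated gestures of one scenario.

    The experiment pools 25 measurements (5 specimens x 5 gestures);
    trials share the planted geometry and differ in their marker-noise
    realizations, each drawn from an independently spawned seed.
    """
    markers0, bones, truth = make_scenario(
        name,
        seed,
        marker_noise_sigma=marker_noise_sigma,
        surface_noise_sigma=surface_noise_sigma,
        n_surface_points=n_surface_points,
    )
    poses = make_screw_motion(truth)
    geom_fixed, geom_moving = default_cluster_geometries()
    trial_seeds = np.random.SeedSequence((seed, 1)).generate_state(n_trials)
    trials = [markers0]
    for k in range(1, n_trials):
        trials.append(
            make_marker_trajectories(
                poses, geom_fixed, geom_moving, marker_noise_sigma,
                int(trial_seeds[k] % 2**31),
            )
        )
    return trials, bones, truth
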