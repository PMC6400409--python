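"""Shared containers and small rigid-body helpers.

Conventions used throughout the package:

* lengths in mm, times in s, angles in degrees at the API surface and
  radians internally;
* a pose ``(R, O)`` maps body coordinates to the fixed (humerus) frame,
  ``x_fixed = R @ x_body + O``;
* rotation matrices are proper orthonormal to at least 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterGeometry",
    "MarkerTrajectorySet",
    "PoseSeries",
    "DegenerateGeometryError",
    "InvalidScenarioError",
    "unit",
    "rotation_about_axis",
    "skew",
    "orthonormality_defect",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested quantity."""


class InvalidScenarioError(ValueError):
    """A synthetic-scenario description violates its invariants."""


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit norm (raises on near-zero input)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-15:
        raise DegenerateGeometryError("cannot normalize a near-zero vector")
    return v / n


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: ``skew(v) @ w == np.cross(v, w)``."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotation_about_axis(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Rotation matrix (or stack of them) about a fixed unit axis.

    This is the matrix form of the axis-angle (Rodrigues) rotation
    formula ``x' = cos(phi) x + (1-cos(phi)) (x.n) n + sin(phi) (n x x)``.
    ``angle_rad`` may be a scalar or a 1-D array; an array yields a
    stack of shape ``(len(angle_rad), 3, 3)``.
    """
    n = unit(axis)
    a = np.asarray(angle_rad, dtype=float)
    K = skew(n)
    c = np.cos(a)[..., None, None]
    s = np.sin(a)[..., None, None]
    eye = np.eye(3)
    return c * eye + (1.0 - c) * np.outer(n, n) + s * K


def orthonormality_defect(R: np.ndarray) -> float:
    """Max-norm deviation of ``R^T R`` from the identity (batch-aware)."""
    R = np.asarray(R, dtype=float)
    RtR = np.einsum("...ji,...jk->...ik", R, R)
    return float(np.abs(RtR - np.eye(3)).max())


@dataclass(frozen=True)
class ClusterGeometry:
    """Rigid marker cluster: marker offsets expressed in the body frame.

    At least three non-collinear markers are required so the cluster
    determines a full 6-DoF pose.
    """

    marker_offsets: np.ndarray  # (m, 3), mm
    marker_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        offsets = np.atleast_2d(np.asarray(self.marker_offsets, dtype=float))
        object.__setattr__(self, "marker_offsets", offsets)
        if offsets.shape[0] < 3 or offsets.shape[1] != 3:
            raise DegenerateGeometryError(
                f"a cluster needs >=3 markers with 3 coordinates, got shape {offsets.shape}"
            )
        if not self.marker_names:
            object.__setattr__(
                self, "marker_names", tuple(f"m{i}" for i in range(offsets.shape[0]))
            )
        if len(self.marker_names) != offsets.shape[0]:
            raise ValueError("marker_names length does not match marker_offsets")
        centred = offsets - offsets.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        if sv[1] <= 1e-9:
            raise DegenerateGeometryError("cluster markers are collinear")

    @property
    def n_markers(self) -> int:
        return self.marker_offsets.shape[0]

    @property
    def rms_radius(self) -> float:
        """RMS marker distance from the cluster centroid, mm."""
        centred = self.marker_offsets - self.marker_offsets.mean(axis=0)
        return float(np.sqrt((centred**2).sum(axis=1).mean()))


@dataclass
class MarkerTrajectorySet:
    """Tracked marker positions for named clusters on a shared time base.

    ``clusters`` maps cluster name -> marker name -> (n_frames, 3) array
    of positions in the laboratory frame, mm.  The time base must be
    strictly increasing and uniformly spaced; gaps are an error, never
    interpolated.
    """

    times: np.ndarray  # (n,), s
    clusters: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if self.times.size > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if np.abs(dts - dts[0]).max() > 1e-9 * max(1.0, abs(float(dts[0]))):
                raise ValueError("times must be uniformly spaced (no missing frames)")
        n = self.times.size
        for cname, markers in self.clusters.items():
            for mname, arr in markers.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"cluster {cname!r} marker {mname!r} has shape {arr.shape}, "
                        f"expected {(n, 3)}"
                    )
                markers[mname] = arr

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need >=2 frames to define dt")
        return float(self.times[1] - self.times[0])

    def cluster_array(self, name: str) -> tuple[tuple[str, ...], np.ndarray]:
        """Return (marker names, (n_frames, m, 3) stacked positions)."""
        markers = self.clusters[name]
        names = tuple(markers.keys())
        return names, np.stack([markers[m] for m in names], axis=1)


@dataclass
class PoseSeries:
    """Time series of rigid poses of a moving body in a fixed frame."""

    times: np.ndarray  # (n,), s
    rotations: np.ndarray  # (n, 3, 3)
    origins: np.ndarray  # (n, 3), mm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.origins = np.asarray(self.origins, dtype=float)
        n = self.times.size
        if self.rotations.shape != (n, 3, 3) or self.origins.shape != (n, 3):
            raise ValueError("inconsistent PoseSeries array shapes")

    def validate(self, tol: float = 1e-9) -> None:
        """Check per-frame orthonormality and positive determinant."""
        defect = orthonormality_defect(self.rotations)
        if defect > tol:
            raise ValueError(f"rotations not orthonormal: defect {defect:.3e} > {tol:g}")
        if np.any(np.linalg.det(self.rotations) <= 0):
            raise ValueError("rotation with non-positive determinant (reflection)")
        if self.times.size > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or np.abs(dts - dts[0]).max() > 1e-9:
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need >=2 frames to define dt")
        return float(self.times[1] - self.times[0])

    def transform_points(self, body_points: np.ndarray) -> np.ndarray:
        """Map (m, 3) body-frame points through every pose -> (n, m, 3)."""
        pts = np.atleast_2d(np.asarray(body_points, dtype=float))
        return np.einsum("nij,mj->nmi", self.rotations, pts) + self.origins[:, None, :]
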