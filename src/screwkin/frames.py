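"""Anatomical joint frame construction from the mean flexion axis.

The elbow frame has its Z axis along the mean flexion axis n_m, its X
axis perpendicular to both n_m and the line from the mean axis point A_m
to the humeral-head sphere centre C_S,

    U_X = (A_m C_S) x n_m / ||(A_m C_S) x n_m||,
    U_Y = U_Z x U_X,
    U_Z = n_m,

and its origin O_beta at the intersection of the flexion-axis line
(through A_m along n_m) with the plane normal to n_m through the
epicondyle midpoint E.  The carpal centre C_W is built the same way at
the wrist: the distal-radius (carpal) trochlea cylinder axis intersected
with the plane normal to it through the styloid midpoint S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateGeometryError, unit
from .fitting import FittedCylinder

__all__ = [
    "Landmarks",
    "AnatomicalFrame",
    "CarpalCentre",
    "build_frame_axes",
    "locate_origin",
    "locate_carpal_centre",
    "build_anatomical_frame",
]


@dataclass(frozen=True)
class Landmarks:
    """Palpable bony landmark points, mm, with their parent body.

    E_M / E_L: medial and lateral humeral epicondyles (humerus).
    S_r / S_u: radial and ulnar styloids (radius-ulna).
    Coordinates are expressed in the humerus frame at the digitization
    (reference) configuration.
    """

    E_M: np.ndarray
    E_L: np.ndarray
    S_r: np.ndarray
    S_u: np.ndarray

    def __post_init__(self) -> None:
        for name in ("E_M", "E_L", "S_r", "S_u"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.allclose(self.E_M, self.E_L):
            raise DegenerateGeometryError("epicondyle landmarks coincide")
        if np.allclose(self.S_r, self.S_u):
            raise DegenerateGeometryError("styloid landmarks coincide")

    @property
    def epicondyle_midpoint(self) -> np.ndarray:
        return 0.5 * (self.E_M + self.E_L)

    @property
    def styloid_midpoint(self) -> np.ndarray:
        return 0.5 * (self.S_r + self.S_u)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Joint frame: orthonormal right-handed triad and origin in the humerus frame."""

    U_X: np.ndarray
    U_Y: np.ndarray
    U_Z: np.ndarray
    origin: np.ndarray  # O_beta, mm
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def rotation(self) -> np.ndarray:
        """Rotation of the joint frame relative to the humerus frame.

        Columns are (U_X, U_Y, U_Z): maps joint-frame coordinates to
        humerus-frame coordinates.
        """
        return np.column_stack([self.U_X, self.U_Y, self.U_Z])

    def to_homogeneous(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.origin
        return T


@dataclass(frozen=True)
class CarpalCentre:
    C_W: np.ndarray  # mm
    S: np.ndarray  # styloid midpoint, mm
    source_cylinder: FittedCylinder | None = None


def build_frame_axes(
    C_S: np.ndarray, A_m: np.ndarray, n_m: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal joint-frame triad (U_X, U_Y, U_Z) with U_Z = n_m."""
    C_S = np.asarray(C_S, dtype=float)
    A_m = np.asarray(A_m, dtype=float)
    U_Z = unit(np.asarray(n_m, dtype=float))
    cross = np.cross(C_S - A_m, U_Z)
    if np.linalg.norm(cross) <= 1e-9:
        raise DegenerateGeometryError(
            "A_m->C_S is parallel to the flexion axis: frame undefined"
        )
    U_X = unit(cross)
    U_Y = np.cross(U_Z, U_X)
    return U_X, U_Y, U_Z


def locate_origin(
    A_m: np.ndarray, n_m: np.ndarray, E_M: np.ndarray, E_L: np.ndarray
) -> np.ndarray:
    """O_beta: flexion-axis line intersected with the epicondyle-midplane.

    The plane passes through E = (E_M + E_L)/2 with normal n_m; since the
    line direction equals the plane normal the intersection always exists:
    ``O_beta = A_m + ((E - A_m) . n_m) n_m``.
    """
    A_m = np.asarray(A_m, dtype=float)
    n = unit(np.asarray(n_m, dtype=float))
    E = 0.5 * (np.asarray(E_M, dtype=float) + np.asarray(E_L, dtype=float))
    return A_m + ((E - A_m) @ n) * n


def locate_carpal_centre(
    cyl: FittedCylinder, S_r: np.ndarray, S_u: np.ndarray
) -> CarpalCentre:
    """C_W: carpal-trochlea cylinder axis meets the styloid-midpoint plane."""
    S = 0.5 * (np.asarray(S_r, dtype=float) + np.asarray(S_u, dtype=float))
    a = np.asarray(cyl.axis_point, dtype=float)
    u = unit(np.asarray(cyl.axis_direction, dtype=float))
    C_W = a + ((S - a) @ u) * u
    return CarpalCentre(C_W=C_W, S=S, source_cylinder=cyl)


def build_anatomical_frame(
    C_S: np.ndarray,
    A_m: np.ndarray,
    n_m: np.ndarray,
    landmarks: Landmarks,
    *,
    limb_side: str = "right",
    provenance: dict | None = None,
) -> AnatomicalFrame:
    """Full joint frame from fitted geometry, mean axis and landmarks.

    ``limb_side`` fixes the sign of n_m so that +U_Z points medially and
    flexion is a positive rotation about U_Z: for a right limb n_m is
    flipped if it points from the medial toward the lateral epicondyle,
    for a left limb the opposite.
    """
    n = unit(np.asarray(n_m, dtype=float))
    medial = landmarks.E_M - landmarks.E_L  # lateral -> medial
    sign = float(np.sign(n @ medial)) or 1.0
    if limb_side == "right":
        n = sign * n
    elif limb_side == "left":
        n = -sign * n
    else:
        raise ValueError(f"limb_side must be 'right' or 'left', got {limb_side!r}")
    U_X, U_Y, U_Z = build_frame_axes(C_S, A_m, n)
    origin = locate_origin(A_m, U_Z, landmarks.E_M, landmarks.E_L)
    return AnatomicalFrame(
        U_X=U_X,
        U_Y=U_Y,
        U_Z=U_Z,
        origin=origin,
        provenance=dict(provenance or {}, limb_side=limb_side),
    )
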