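"""Least-squares sphere and cylinder fitting for articular-surface patches.

Both fits minimize orthogonal (geometric) distance: an algebraic
closed-form fit provides the starting point and ``scipy.optimize``
refines the residuals ``||p - c|| - r`` (sphere) and
``dist(p, axis) - r`` (cylinder).  The humeral head yields the sphere
centre C_S; the humeral and radial trochleae yield cylinder axes used as
candidate flexion/carpal axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import DegenerateGeometryError, unit

__all__ = ["FittedSphere", "FittedCylinder", "fit_sphere", "fit_cylinder", "NarrowArcWarning"]


class NarrowArcWarning(UserWarning):
    """Cylinder patch subtends a small arc: axis weakly constrained."""


@dataclass(frozen=True)
class FittedSphere:
    center: np.ndarray  # C_S, mm
    radius: float  # mm
    rms_residual: float  # mm
    n_points: int


@dataclass(frozen=True)
class FittedCylinder:
    axis_point: np.ndarray  # mm; projection of the point centroid onto the axis
    axis_direction: np.ndarray  # unit
    radius: float  # mm
    rms_residual: float  # mm
    n_points: int
    arc_extent_deg: float = float("nan")
    narrow_arc: bool = False


def _check_not_coplanar(points: np.ndarray, what: str) -> None:
    centred = points - points.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError(f"{what}: points are coplanar/collinear")


def fit_sphere(points: np.ndarray) -> FittedSphere:
    """Best-fit sphere minimizing sum of (||p - c|| - r)^2.

    Requires >= 4 non-coplanar points.  Initialization is the algebraic
    (Kasa) fit, refined by geometric least squares.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if p.shape[0] < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    _check_not_coplanar(p, "sphere fit")

    # algebraic: ||p||^2 = 2 c.p + (r^2 - ||c||^2)
    A = np.column_stack([2.0 * p, np.ones(p.shape[0])])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def resid(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    fit = least_squares(resid, np.append(c0, r0), method="lm", xtol=1e-14, ftol=1e-14)
    c, r = fit.x[:3], float(fit.x[3])
    if r <= 0:
        raise DegenerateGeometryError("sphere fit collapsed to non-positive radius")
    rms = float(np.sqrt((resid(fit.x) ** 2).mean()))
    return FittedSphere(center=c, radius=r, rms_residual=rms, n_points=p.shape[0])


def _canonical_direction(u: np.ndarray) -> np.ndarray:
    """Deterministic axis sign: largest-magnitude component positive."""
    u = unit(u)
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0 or (u[k] == 0 and u[0] < 0):
        u = -u
    return u


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _circle_fit_2d(xy: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kasa) circle fit; returns (center, radius, rms)."""
    A = np.column_stack([2.0 * xy, np.ones(xy.shape[0])])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:2]
    r = float(np.sqrt(max(sol[2] + c @ c, 1e-12)))
    rms = float(np.sqrt(((np.linalg.norm(xy - c, axis=1) - r) ** 2).mean()))
    return c, r, rms


def _axis_distance(p: np.ndarray, a: np.ndarray, u: np.ndarray) -> np.ndarray:
    rel = p - a
    along = rel @ u
    return np.linalg.norm(rel - along[:, None] * u[None, :], axis=1)


def _arc_extent_deg(p: np.ndarray, a: np.ndarray, u: np.ndarray) -> float:
    """Angular extent of the patch around the fitted axis (360 - largest gap)."""
    e1, e2 = _perp_basis(u)
    rel = p - a
    ang = np.sort(np.arctan2(rel @ e2, rel @ e1))
    if ang.size < 2:
        return 0.0
    gaps = np.diff(np.append(ang, ang[0] + 2.0 * np.pi))
    return float(np.degrees(2.0 * np.pi - gaps.max()))


def fit_cylinder(points: np.ndarray) -> FittedCylinder:
    """Best-fit cylinder minimizing sum of (dist(p, axis) - r)^2.

    Requires >= 6 points not lying on a line or plane.  The direction is
    initialized from the principal directions of the point covariance
    (each eigenvector tried, best algebraic score kept) and refined
    jointly with the axis offset and radius.  A patch subtending < 30
    degrees of arc raises :class:`NarrowArcWarning` and sets the
    ``narrow_arc`` flag.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if p.shape[0] < 6:
        raise DegenerateGeometryError("cylinder fit needs >= 6 points")
    _check_not_coplanar(p, "cylinder fit")
    c0 = p.mean(axis=0)
    centred = p - c0

    # candidate directions: eigenvectors of the covariance
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    best = None
    for u0 in Vt:
        e1, e2 = _perp_basis(u0)
        xy = np.column_stack([centred @ e1, centred @ e2])
        try:
            c2d, r2d, rms = _circle_fit_2d(xy)
        except Exception:
            continue
        if best is None or rms < best[0]:
            best = (rms, u0, e1, e2, c2d, r2d)
    if best is None:
        raise DegenerateGeometryError("cylinder initialization failed")
    _, u0, e1, e2, c2d, r2d = best

    # params: direction perturbation (alpha, beta) around u0, in-plane axis
    # offset (c1, c2) from the centroid, radius r
    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        u = unit(u0 + x[0] * e1 + x[1] * e2)
        a = c0 + x[2] * e1 + x[3] * e2
        return a, u, x[4]

    def resid(x: np.ndarray) -> np.ndarray:
        a, u, r = unpack(x)
        return _axis_distance(p, a, u) - r

    x0 = np.array([0.0, 0.0, c2d[0], c2d[1], r2d])
    fit = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=2000)
    a, u, r = unpack(fit.x)
    if r <= 0:
        raise DegenerateGeometryError("cylinder fit collapsed to non-positive radius")
    u = _canonical_direction(u)
    # canonical axis point: projection of the centroid onto the axis
    a = a + ((c0 - a) @ u) * u
    rms = float(np.sqrt((resid(fit.x) ** 2).mean()))
    extent = _arc_extent_deg(p, a, u)
    narrow = extent < 30.0
    if narrow:
        warnings.warn(
            f"cylinder patch subtends only {extent:.1f} deg of arc; "
            "axis direction is weakly constrained",
            NarrowArcWarning,
            stacklevel=2,
        )
    return FittedCylinder(
        axis_point=a,
        axis_direction=u,
        radius=float(r),
        rms_residual=rms,
        n_points=p.shape[0],
        arc_extent_deg=extent,
        narrow_arc=narrow,
    )
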