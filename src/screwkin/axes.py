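"""Comparison of the surface-fit flexion axis with the motion-derived axis.

The humeral-trochlea best-fit cylinder axis is intersected with the
U_X U_Y plane of the anatomical frame (the plane through O_beta normal
to the mean flexion axis); the in-plane distance from that intersection
point to O_beta and the unsigned angle between the two axis directions
quantify how far the articular-surface axis sits from the axis the bones
actually rotate about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dof import t_critical
from .fitting import FittedCylinder
from .frames import AnatomicalFrame

__all__ = ["AxisComparison", "compare_axes", "multi_specimen_summary"]


@dataclass(frozen=True)
class AxisComparison:
    in_plane_distance: float  # mm
    angular_difference: float  # degrees, in [0, 90]
    plane_point: np.ndarray  # O_beta
    cylinder_intersection: np.ndarray  # P_cyl


def compare_axes(cyl: FittedCylinder, frame: AnatomicalFrame) -> AxisComparison:
    """Distance and angle between the cylinder axis and the mean flexion axis.

    The distance is ``||P_cyl - O_beta||`` with P_cyl the intersection of
    the cylinder axis with the plane through O_beta spanned by U_X, U_Y;
    the angle is ``arccos(|u_cyl . n_m|)`` so the axis orientation sign
    never matters.
    """
    u = np.asarray(cyl.axis_direction, dtype=float)
    a = np.asarray(cyl.axis_point, dtype=float)
    n = frame.U_Z
    denom = float(u @ n)
    if abs(denom) <= 1e-6:
        raise ValueError(
            "cylinder axis is parallel to the U_X U_Y plane: no intersection"
        )
    s = float((frame.origin - a) @ n) / denom
    P_cyl = a + s * u
    dist = float(np.linalg.norm(P_cyl - frame.origin))
    ang = float(np.degrees(np.arccos(np.clip(abs(float(u @ n)) / np.linalg.norm(u), 0.0, 1.0))))
    return AxisComparison(
        in_plane_distance=dist,
        angular_difference=ang,
        plane_point=frame.origin.copy(),
        cylinder_intersection=P_cyl,
    )


def multi_specimen_summary(
    comparisons: list[AxisComparison], alpha: float = 0.05
) -> dict[str, float]:
    """Across-specimen means with Student-t half-widths (two-tailed).

    Returns mean_distance_mm / distance_halfwidth_mm and
    mean_angle_deg / angle_halfwidth_deg with df = n - 1.
    """
    if len(comparisons) < 2:
        raise ValueError("need >= 2 comparisons to summarize")
    d = np.array([c.in_plane_distance for c in comparisons])
    a = np.array([c.angular_difference for c in comparisons])
    n = d.size
    t = t_critical(n - 1, alpha)
    return {
        "n": n,
        "mean_distance_mm": float(d.mean()),
        "distance_halfwidth_mm": float(t * d.std(ddof=1) / np.sqrt(n)),
        "mean_angle_deg": float(a.mean()),
        "angle_halfwidth_deg": float(t * a.std(ddof=1) / np.sqrt(n)),
    }
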