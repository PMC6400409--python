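"""Six-DoF displacement decomposition in the anatomical frame.

Each relative pose is re-expressed in the joint frame as a displacement
from a reference (maximum-extension) pose, measured about the joint
origin O_beta.  The rotation part is factored as an intrinsic Z-Y-X
Tait-Bryan cascade ``R = Rot_Z(R_Z) Rot_Y(R_Y) Rot_X(R_X)`` so the first
extracted angle is flexion; the translation part is the displacement of
the material point at O_beta, expressed on (U_X, U_Y, U_Z):

    R_Z  flexion-extension          T_Z  medial-lateral translation
    R_Y  adduction-abduction        T_Y  proximal-distal translation
    R_X  internal-external rotation T_X  anterior-posterior translation

Multi-trial curves are parameterized by the instantaneous flexion angle
(trials have different actuation speeds), linearly interpolated onto a
common grid, and aggregated with Student-t confidence half-widths
``t_{1-alpha/2, n-1} s / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PoseSeries
from .frames import AnatomicalFrame

__all__ = [
    "DOF_NAMES",
    "DofSamples",
    "DofCurves",
    "pose_in_joint_frame",
    "displacement_series",
    "flexion_angle_series",
    "decompose_tait_bryan",
    "decompose_series",
    "aggregate_curves",
    "t_critical",
    "significance_screen",
    "default_rotation_uncertainty_deg",
    "GIMBAL_LIMIT_DEG",
]

DOF_NAMES = ("R_Z", "R_Y", "R_X", "T_X", "T_Y", "T_Z")
GIMBAL_LIMIT_DEG = 89.9


def pose_in_joint_frame(
    R: np.ndarray,
    O: np.ndarray,
    frame: AnatomicalFrame,
    R_ref: np.ndarray,
    O_ref: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement of a pose from the reference, in joint-frame coordinates.

    Returns ``(D, t)``: the rotation displacement ``D = Q^T R R_ref^T Q``
    and the translation of the material point coinciding with O_beta in
    the reference configuration, ``t = Q^T (R R_ref^T (O_beta - O_ref) +
    O - O_beta)``, where Q has columns (U_X, U_Y, U_Z).  Batch-aware in
    the leading axis of R and O.
    """
    Q = frame.rotation
    R = np.asarray(R, dtype=float)
    O = np.asarray(O, dtype=float)
    Rd = np.einsum("...ij,kj->...ik", R, np.asarray(R_ref, dtype=float))
    D = np.einsum("ji,...jk,kl->...il", Q, Rd, Q)
    carried = np.einsum("...ij,j->...i", Rd, frame.origin - np.asarray(O_ref, float))
    t = np.einsum("ji,...j->...i", Q, carried + O - frame.origin)
    return D, t


def decompose_tait_bryan(
    D: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Six displacement components from a joint-frame displacement.

    Returns ``(angles_deg, gimbal_flag)`` where ``angles_deg`` has
    columns (R_Z, R_Y, R_X, T_X, T_Y, T_Z) — rotations in degrees,
    translations in mm — and ``gimbal_flag`` marks samples with
    ``|R_Y|`` within 0.1 deg of the Z-Y-X gimbal singularity.
    Batch-aware.
    """
    D = np.asarray(D, dtype=float)
    t = np.asarray(t, dtype=float)
    single = D.ndim == 2
    if single:
        D = D[None]
        t = t[None]
    sy = np.clip(-D[..., 2, 0], -1.0, 1.0)
    R_Y = np.arcsin(sy)
    R_Z = np.arctan2(D[..., 1, 0], D[..., 0, 0])
    R_X = np.arctan2(D[..., 2, 1], D[..., 2, 2])
    out = np.column_stack(
        [
            np.degrees(R_Z),
            np.degrees(R_Y),
            np.degrees(R_X),
            t[..., 0],
            t[..., 1],
            t[..., 2],
        ]
    )
    gimbal = np.abs(np.degrees(R_Y)) > GIMBAL_LIMIT_DEG
    if single:
        return out[0], bool(gimbal[0])
    return out, gimbal


def compose_tait_bryan(
    R_Z_deg: float, R_Y_deg: float, R_X_deg: float
) -> np.ndarray:
    """Forward composition ``Rot_Z(R_Z) Rot_Y(R_Y) Rot_X(R_X)`` (degrees)."""
    cz, sz = np.cos(np.radians(R_Z_deg)), np.sin(np.radians(R_Z_deg))
    cy, sy = np.cos(np.radians(R_Y_deg)), np.sin(np.radians(R_Y_deg))
    cx, sx = np.cos(np.radians(R_X_deg)), np.sin(np.radians(R_X_deg))
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    return Rz @ Ry @ Rx


def flexion_angle_series(
    poses: PoseSeries,
    frame: AnatomicalFrame,
    C_W: np.ndarray,
    R_ref: np.ndarray,
    O_ref: np.ndarray,
    *,
    zero_direction: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous flexion angle (degrees) from the tracked carpal centre.

    C_W (given in the humerus frame at the reference configuration) is
    attached to the moving body; its position is projected into the
    U_X U_Y plane and the signed angle about +U_Z from a zero-flexion
    reference direction is returned.  The default reference direction is
    the projected forearm direction at the reference pose, so the
    reference pose reads zero flexion; ``zero_direction`` (a vector in
    the humerus frame) overrides it.
    """
    C_W = np.asarray(C_W, dtype=float)
    R_ref = np.asarray(R_ref, dtype=float)
    O_ref = np.asarray(O_ref, dtype=float)
    body = R_ref.T @ (C_W - O_ref)  # carpal centre in moving-body coordinates
    pos = np.einsum("nij,j->ni", poses.rotations, body) + poses.origins
    rel = pos - frame.origin
    vx = rel @ frame.U_X
    vy = rel @ frame.U_Y
    if zero_direction is None:
        ref_rel = C_W - frame.origin
    else:
        ref_rel = np.asarray(zero_direction, dtype=float)
    rx = float(ref_rel @ frame.U_X)
    ry = float(ref_rel @ frame.U_Y)
    if np.hypot(rx, ry) <= 1e-6 or np.any(np.hypot(vx, vy) <= 1e-6):
        raise ValueError(
            "forearm direction projects onto the flexion axis: flexion angle undefined"
        )
    # signed angle about +U_Z from the reference direction to the current one
    ang = np.arctan2(rx * vy - ry * vx, rx * vx + ry * vy)
    return np.degrees(np.unwrap(ang))


@dataclass
class DofSamples:
    """Per-frame DoF decomposition of one trial, indexed by flexion angle."""

    trial_id: str
    data: pd.DataFrame  # columns: time, flexion_deg, R_Z, R_Y, R_X, T_X, T_Y, T_Z
    gimbal_flags: np.ndarray


def displacement_series(
    poses: PoseSeries,
    frame: AnatomicalFrame,
    R_ref: np.ndarray,
    O_ref: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched joint-frame displacement (D stack, t stack) of a pose series."""
    return pose_in_joint_frame(poses.rotations, poses.origins, frame, R_ref, O_ref)


def decompose_series(
    poses: PoseSeries,
    frame: AnatomicalFrame,
    C_W: np.ndarray,
    *,
    R_ref: np.ndarray | None = None,
    O_ref: np.ndarray | None = None,
    trial_id: str = "trial",
) -> DofSamples:
    """Full per-frame decomposition of a trial into the six DoF samples.

    The reference pose defaults to the first frame (maximum extension).
    """
    if R_ref is None:
        R_ref = poses.rotations[0]
    if O_ref is None:
        O_ref = poses.origins[0]
    D, t = displacement_series(poses, frame, R_ref, O_ref)
    comps, gimbal = decompose_tait_bryan(D, t)
    flexion = flexion_angle_series(poses, frame, C_W, R_ref, O_ref)
    df = pd.DataFrame(comps, columns=list(DOF_NAMES))
    df.insert(0, "flexion_deg", flexion)
    df.insert(0, "time", poses.times)
    return DofSamples(trial_id=trial_id, data=df, gimbal_flags=gimbal)


@dataclass
class DofCurves:
    """Flexion-gridded across-trial means and confidence half-widths."""

    flexion_grid: np.ndarray  # degrees, strictly increasing
    means: dict[str, np.ndarray]
    half_widths: dict[str, np.ndarray]
    n_trials: int
    n_used: np.ndarray  # trials contributing per grid point
    t_critical: float  # for the full trial count
    alpha: float
    excluded_points: int = 0  # (trial, grid point) pairs outside a trial's range

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"flexion_deg": self.flexion_grid}
        for dof in DOF_NAMES:
            if dof in self.means:
                cols[f"{dof}_mean"] = self.means[dof]
                cols[f"{dof}_halfwidth"] = self.half_widths[dof]
        cols["n_trials_used"] = self.n_used
        return pd.DataFrame(cols)


def t_critical(df: int, alpha: float) -> float:
    """Two-tailed Student-t critical value ``t_{1-alpha/2, df}``."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def aggregate_curves(
    trials: list[DofSamples],
    grid: np.ndarray,
    alpha: float = 0.05,
    *,
    dofs: tuple[str, ...] = DOF_NAMES,
) -> DofCurves:
    """Interpolate each trial onto a common flexion grid and average.

    Per grid point: mean over the trials whose flexion range covers it
    and half-width ``t_{1-alpha/2, n-1} s / sqrt(n)`` with s the
    across-trial standard deviation.  Grid points outside a trial's
    range exclude that trial there (counted in ``excluded_points``);
    points covered by fewer than two trials get NaN half-widths.
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to aggregate")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("flexion grid must be 1-D and strictly increasing")
    n = len(trials)
    values = {dof: np.full((n, grid.size), np.nan) for dof in dofs}
    for k, trial in enumerate(trials):
        flex = trial.data["flexion_deg"].to_numpy()
        order = np.argsort(flex, kind="stable")
        fx = flex[order]
        inside = (grid >= fx[0]) & (grid <= fx[-1])
        for dof in dofs:
            y = trial.data[dof].to_numpy()[order]
            values[dof][k, inside] = np.interp(grid[inside], fx, y)
    counts = np.sum(np.isfinite(values[dofs[0]]), axis=0)
    excluded = int(n * grid.size - counts.sum())

    means: dict[str, np.ndarray] = {}
    hws: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        for dof in dofs:
            v = values[dof]
            m = np.nanmean(v, axis=0)
            s = np.full(grid.size, np.nan)
            ok = counts >= 2
            s[ok] = np.nanstd(v[:, ok], axis=0, ddof=1)
            hw = np.full(grid.size, np.nan)
            for cnt in np.unique(counts[ok]):
                sel = counts == cnt
                hw[sel] = t_critical(int(cnt) - 1, alpha) * s[sel] / np.sqrt(cnt)
            means[dof] = m
            hws[dof] = hw
    return DofCurves(
        flexion_grid=grid,
        means=means,
        half_widths=hws,
        n_trials=n,
        n_used=counts,
        t_critical=t_critical(n - 1, alpha),
        alpha=alpha,
        excluded_points=excluded,
    )


def default_rotation_uncertainty_deg(
    marker_sigma_mm: float = 0.012, cluster_rms_radius_mm: float = 30.0
) -> float:
    """Angular equivalent of the marker uncertainty over the cluster span.

    A marker error of sigma at RMS lever arm rho tilts the fitted cluster
    orientation by about sigma*sqrt(2)/rho radians (two clusters
    contribute independently); this serves as the rotation-channel
    measurement uncertainty when none is stated.
    """
    return float(np.degrees(np.sqrt(2.0) * marker_sigma_mm / cluster_rms_radius_mm))


def significance_screen(
    curves: DofCurves,
    *,
    translation_uncertainty_mm: float = 0.012,
    rotation_uncertainty_deg: float | None = None,
) -> dict[str, bool]:
    """Flag DoFs whose band-adjusted magnitude exceeds measurement uncertainty.

    A DoF is significant when ``max_grid (|mean| - half_width)`` exceeds
    the measurement uncertainty of its channel (mm for translations,
    degrees for rotations).  Flexion R_Z, the driven motion, is not
    screened.
    """
    if rotation_uncertainty_deg is None:
        rotation_uncertainty_deg = default_rotation_uncertainty_deg()
    out: dict[str, bool] = {}
    for dof in curves.means:
        if dof == "R_Z":
            continue
        u = translation_uncertainty_mm if dof.startswith("T") else rotation_uncertainty_deg
        m = curves.means[dof]
        hw = curves.half_widths[dof]
        ok = np.isfinite(m) & np.isfinite(hw)
        score = np.abs(m[ok]) - hw[ok]
        out[dof] = bool(score.size and score.max() > u)
    return out
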