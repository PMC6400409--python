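"""Rigid-pose reconstruction from marker-cluster trajectories.

Per frame, the pose of each cluster's body frame in laboratory
coordinates is recovered by a least-squares rigid (Procrustes/Kabsch)
fit of the known body-frame marker offsets to the observed marker
positions, restricted to proper rotations.  The relative pose of the
moving bone in the fixed bone frame is then the composition
``R = R_f^T R_m``, ``O = R_f^T (t_m - t_f)``, which is invariant under
any common rigid motion of the laboratory frame.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ClusterGeometry,
    DegenerateGeometryError,
    MarkerTrajectorySet,
    PoseSeries,
)

__all__ = ["fit_rigid_transform", "fit_rigid_transform_batch", "relative_pose_series"]


def _kabsch_from_cross(H: np.ndarray) -> np.ndarray:
    """Proper rotation maximizing trace(R^T H) for cross-covariance H.

    Batch-aware: ``H`` may be (..., 3, 3).  Reflections are corrected by
    flipping the singular vector of the smallest singular value.
    """
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", U, Vt))
    D = np.zeros(H.shape[:-2] + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = det
    # R = V D U^T for H = sum_k p_k q_k^T
    return np.einsum("...ji,...jk,...lk->...il", Vt, D, U)


def fit_rigid_transform(
    reference_points: np.ndarray, observed_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping reference onto observed points.

    Minimizes ``sum_k ||R p_k + t - q_k||^2`` over proper rotations R and
    translations t.

    Parameters
    ----------
    reference_points, observed_points:
        (m, 3) arrays with m >= 3 non-collinear points, equal counts.

    Returns
    -------
    (R, t, rms_residual):
        rotation (3, 3), translation (3,), and the RMS of the per-point
        residual norms in mm.
    """
    p = np.atleast_2d(np.asarray(reference_points, dtype=float))
    q = np.atleast_2d(np.asarray(observed_points, dtype=float))
    if p.shape != q.shape:
        raise ValueError(f"point-count mismatch: {p.shape} vs {q.shape}")
    if p.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.svd(pc, compute_uv=False)[1] <= 1e-9:
        raise DegenerateGeometryError("reference points are collinear")
    H = pc.T @ qc
    R = _kabsch_from_cross(H)
    t = q.mean(axis=0) - R @ p.mean(axis=0)
    resid = q - (p @ R.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return R, t, rms


def fit_rigid_transform_batch(
    reference_points: np.ndarray, observed_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rigid fit of one reference cluster to many frames.

    Parameters
    ----------
    reference_points : (m, 3)
    observed_points : (n, m, 3)

    Returns
    -------
    (R, t, rms) with shapes (n, 3, 3), (n, 3), (n,).
    """
    p = np.asarray(reference_points, dtype=float)
    q = np.asarray(observed_points, dtype=float)
    if p.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    pc = p - p.mean(axis=0)
    if np.linalg.svd(pc, compute_uv=False)[1] <= 1e-9:
        raise DegenerateGeometryError("reference points are collinear")
    qm = q.mean(axis=1)
    qc = q - qm[:, None, :]
    H = np.einsum("mi,nmj->nij", pc, qc)
    R = _kabsch_from_cross(H)
    t = qm - np.einsum("nij,j->ni", R, p.mean(axis=0))
    fitted = np.einsum("nij,mj->nmi", R, p) + t[:, None, :]
    rms = np.sqrt(((q - fitted) ** 2).sum(axis=2).mean(axis=1))
    return R, t, rms


def relative_pose_series(
    markers: MarkerTrajectorySet,
    geom_fixed: ClusterGeometry,
    geom_moving: ClusterGeometry,
    *,
    fixed_cluster: str = "fixed",
    moving_cluster: str = "moving",
) -> PoseSeries:
    """Pose series of the moving bone expressed in the fixed bone frame.

    Both clusters are fitted in laboratory coordinates at every frame and
    the relative (moving-in-fixed) pose is composed; the result is
    invariant to common rigid motion of the lab frame.  Frames with
    non-finite marker data are rejected with the offending frame index.
    """
    for cname, geom in ((fixed_cluster, geom_fixed), (moving_cluster, geom_moving)):
        if cname not in markers.clusters:
            raise KeyError(f"cluster {cname!r} not present in trajectory set")
        names, arr = markers.cluster_array(cname)
        if len(names) != geom.n_markers:
            raise ValueError(
                f"cluster {cname!r} has {len(names)} markers, geometry defines "
                f"{geom.n_markers}"
            )
        bad = np.nonzero(~np.isfinite(arr).all(axis=(1, 2)))[0]
        if bad.size:
            raise ValueError(
                f"cluster {cname!r}: missing/non-finite markers at frame {int(bad[0])}"
            )

    _, obs_f = markers.cluster_array(fixed_cluster)
    _, obs_m = markers.cluster_array(moving_cluster)
    Rf, tf, _ = fit_rigid_transform_batch(geom_fixed.marker_offsets, obs_f)
    Rm, tm, _ = fit_rigid_transform_batch(geom_moving.marker_offsets, obs_m)
    R = np.einsum("nji,njk->nik", Rf, Rm)  # Rf^T Rm
    O = np.einsum("nji,nj->ni", Rf, tm - tf)
    return PoseSeries(times=markers.times.copy(), rotations=R, origins=O)
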