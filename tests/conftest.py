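"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from screwkin.core import unit
from screwkin.synthetic import GroundTruth, smoothstep


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator, angle_range=(0.01, 3.0)) -> np.ndarray:
    """Uniform-axis rotation with angle drawn from the given range (rad)."""
    axis = unit(rng.normal(size=3))
    angle = rng.uniform(*angle_range)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def quat_oracle(R: np.ndarray) -> np.ndarray:
    """Independent quaternion (S, L, M, N) extraction via scipy."""
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    return q if q[0] >= 0 else -q


def horn_rigid_fit(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absolute orientation via Horn's quaternion-eigenvalue method.

    Independent of the SVD (Kabsch) route used by the implementation.
    """
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    M = pc.T @ qc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    t = q.mean(axis=0) - R @ p.mean(axis=0)
    return R, t


def pitch_screw_truth(
    total_translation: float = 0.457,
    max_flexion: float = 91.0,
    *,
    duration: float = 40.0,
    dt: float = 0.01,
) -> GroundTruth:
    """Constant-pitch screw gesture: flexion ramp with proportional translation."""
    pitch = total_translation / np.radians(max_flexion)  # mm per rad
    return GroundTruth(
        axis_point=np.zeros(3),
        axis_direction=unit(np.array([0.08, -0.06, 1.0])),
        angle_profile=lambda t: max_flexion * smoothstep(np.asarray(t, float) / duration),
        axial_translation_profile=lambda f: pitch * np.radians(np.asarray(f, dtype=float)),
        marker_noise_sigma=0.0,
        dt=dt,
        duration=duration,
        name="pitch-screw",
    )


def point_line_distance(points: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray) -> np.ndarray:
    rel = np.atleast_2d(points) - line_point
    along = rel @ line_dir
    return np.linalg.norm(rel - along[:, None] * line_dir[None, :], axis=1)
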