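"""File formats: TRC and CSV marker trajectories, PLY surfaces, JSON/YAML.

TRC is the tab-delimited motion-capture interchange format (header with
DataRate/NumFrames/NumMarkers/Units); surfaces are ascii PLY point
clouds read and written through ``trimesh``; landmarks, ground truth,
frames and reports are JSON; cluster-to-bone marker assignment is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml
from trimesh.exchange.ply import export_ply

from .core import ClusterGeometry, MarkerTrajectorySet
from .frames import AnatomicalFrame, CarpalCentre, Landmarks
from .synthetic import GroundTruth, SyntheticBoneSet

__all__ = [
    "write_trc",
    "read_trc",
    "write_markers_csv",
    "read_markers_csv",
    "write_ply",
    "read_ply",
    "write_bone_set",
    "read_bone_set",
    "write_cluster_config",
    "read_cluster_config",
    "write_ground_truth",
    "read_ground_truth",
    "write_frame_json",
    "write_curves_csv",
    "plot_curves",
    "write_screw_csv",
]


def _flat_markers(markers: MarkerTrajectorySet) -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    for cluster in markers.clusters.values():
        for name, arr in cluster.items():
            if name in flat:
                raise ValueError(f"duplicate marker name {name!r} across clusters")
            flat[name] = arr
    return flat


def write_trc(markers: MarkerTrajectorySet, path: str | Path) -> None:
    """Write marker trajectories as a TRC file (units mm)."""
    path = Path(path)
    flat = _flat_markers(markers)
    names = list(flat)
    n = markers.n_frames
    rate = 1.0 / markers.dt if n > 1 else 100.0
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:.1f}\t{rate:.1f}\t{n}\t{len(names)}\tmm\t{rate:.1f}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(len(names))),
        "",
    ]
    data = np.column_stack([flat[m] for m in names])
    with path.open("w") as fh:
        fh.write("\n".join(lines))
        for k in range(n):
            row = "\t".join(f"{x:.8f}" for x in data[k])
            fh.write(f"{k + 1}\t{markers.times[k]:.6f}\t{row}\n")


def read_trc(
    path: str | Path, clusters: dict[str, list[str]]
) -> MarkerTrajectorySet:
    """Read a TRC file, grouping markers into the given clusters."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    header = lines[3].split("\t")
    names = [h for h in header[2:] if h.strip()]
    body = [ln for ln in lines[5:] if ln.strip()]
    rows = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in body])
    times = rows[:, 0]
    coords = rows[:, 1 : 1 + 3 * len(names)]
    flat = {m: coords[:, 3 * i : 3 * i + 3] for i, m in enumerate(names)}
    return _group_markers(times, flat, clusters)


def _group_markers(
    times: np.ndarray, flat: dict[str, np.ndarray], clusters: dict[str, list[str]]
) -> MarkerTrajectorySet:
    grouped: dict[str, dict[str, np.ndarray]] = {}
    for cname, mnames in clusters.items():
        missing = [m for m in mnames if m not in flat]
        if missing:
            raise KeyError(f"cluster {cname!r}: markers not found in file: {missing}")
        grouped[cname] = {m: flat[m] for m in mnames}
    return MarkerTrajectorySet(times=times, clusters=grouped)


def write_markers_csv(markers: MarkerTrajectorySet, path: str | Path) -> None:
    """Plain CSV with columns time, <marker>_x, <marker>_y, <marker>_z."""
    flat = _flat_markers(markers)
    cols: dict[str, np.ndarray] = {"time": markers.times}
    for name, arr in flat.items():
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8f")


def read_markers_csv(
    path: str | Path, clusters: dict[str, list[str]]
) -> MarkerTrajectorySet:
    df = pd.read_csv(path)
    times = df["time"].to_numpy()
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    flat = {
        m: df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy() for m in names
    }
    return _group_markers(times, flat, clusters)


def write_ply(points: np.ndarray, path: str | Path) -> None:
    """Write a point cloud as ascii PLY."""
    data = export_ply(trimesh.PointCloud(np.asarray(points, dtype=float)), encoding="ascii")
    Path(path).write_bytes(data)


def read_ply(path: str | Path) -> np.ndarray:
    """Read the vertices of a PLY or STL file as an (n, 3) array."""
    loaded = trimesh.load(str(path))
    return np.asarray(loaded.vertices, dtype=float)


def write_bone_set(bones: SyntheticBoneSet, out_dir: str | Path) -> None:
    """Per-region ascii PLY files plus a landmarks JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for region, pts in bones.regions.items():
        write_ply(pts, out_dir / f"{region}.ply")
    lm = bones.landmarks
    payload = {
        "E_M": lm.E_M.tolist(),
        "E_L": lm.E_L.tolist(),
        "S_r": lm.S_r.tolist(),
        "S_u": lm.S_u.tolist(),
        "bodies": {"E_M": "humerus", "E_L": "humerus", "S_r": "radius-ulna", "S_u": "radius-ulna"},
        "degenerate_extent": bones.degenerate_extent,
    }
    (out_dir / "landmarks.json").write_text(json.dumps(payload, indent=2))


def read_bone_set(in_dir: str | Path) -> tuple[dict[str, np.ndarray], Landmarks]:
    """Read per-region PLY clouds and the landmarks JSON from a directory."""
    in_dir = Path(in_dir)
    regions = {
        p.stem: read_ply(p) for p in sorted(in_dir.glob("*.ply"))
    }
    lm_path = in_dir / "landmarks.json"
    if not lm_path.exists():
        raise FileNotFoundError(f"missing landmarks file: {lm_path}")
    raw = json.loads(lm_path.read_text())
    for key in ("E_M", "E_L", "S_r", "S_u"):
        if key not in raw:
            raise KeyError(f"landmarks.json is missing required landmark {key!r}")
    landmarks = Landmarks(
        E_M=np.array(raw["E_M"]),
        E_L=np.array(raw["E_L"]),
        S_r=np.array(raw["S_r"]),
        S_u=np.array(raw["S_u"]),
    )
    return regions, landmarks


def write_cluster_config(
    geom_fixed: ClusterGeometry, geom_moving: ClusterGeometry, path: str | Path
) -> None:
    """YAML mapping of cluster names to bodies, markers and body-frame offsets."""
    payload = {
        "clusters": {
            "fixed": {
                "body": "humerus",
                "markers": {
                    n: [float(x) for x in off]
                    for n, off in zip(geom_fixed.marker_names, geom_fixed.marker_offsets)
                },
            },
            "moving": {
                "body": "radius-ulna",
                "markers": {
                    n: [float(x) for x in off]
                    for n, off in zip(geom_moving.marker_names, geom_moving.marker_offsets)
                },
            },
        }
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_cluster_config(path: str | Path) -> tuple[ClusterGeometry, ClusterGeometry]:
    raw = yaml.safe_load(Path(path).read_text())
    geoms = {}
    for cname in ("fixed", "moving"):
        markers = raw["clusters"][cname]["markers"]
        geoms[cname] = ClusterGeometry(
            marker_offsets=np.array(list(markers.values()), dtype=float),
            marker_names=tuple(markers.keys()),
        )
    return geoms["fixed"], geoms["moving"]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON ground truth: axis, noise, reference pose and sampled profiles."""
    R0, O0 = truth.reference_pose
    fmin, fmax = truth.flexion_range
    grid = np.linspace(fmin, fmax, 183)
    profiles = truth.planted_dof_profiles(grid)
    t_sample = np.linspace(0.0, truth.duration, 401)
    payload = {
        "name": truth.name,
        "seed": truth.seed,
        "axis_point_mm": truth.axis_point.tolist(),
        "axis_direction": truth.axis_direction.tolist(),
        "marker_noise_sigma_mm": truth.marker_noise_sigma,
        "surface_noise_sigma_mm": truth.surface_noise_sigma,
        "dt_s": truth.dt,
        "duration_s": truth.duration,
        "reference_rotation": R0.tolist(),
        "reference_origin_mm": O0.tolist(),
        "frame_rotation": truth.frame_rotation.tolist(),
        "frame_origin_mm": truth.frame_origin.tolist(),
        "planted": truth.planted,
        "flexion_grid_deg": grid.tolist(),
        "dof_profiles": {k: v.tolist() for k, v in profiles.items()},
        "angle_profile": {
            "time_s": t_sample.tolist(),
            "flexion_deg": np.asarray(truth.angle_profile(t_sample)).tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    for key in ("reference_rotation", "reference_origin_mm", "axis_direction", "axis_point_mm"):
        if key in raw:
            raw[key] = np.array(raw[key], dtype=float)
    return raw


def write_frame_json(
    frame: AnatomicalFrame, carpal: CarpalCentre | None, path: str | Path
) -> None:
    """Anatomical frame as a 4x4 homogeneous transform plus named points."""
    payload: dict = {
        "transform": frame.to_homogeneous().tolist(),
        "U_X": frame.U_X.tolist(),
        "U_Y": frame.U_Y.tolist(),
        "U_Z": frame.U_Z.tolist(),
        "O_beta_mm": frame.origin.tolist(),
        "provenance": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in frame.provenance.items()
        },
    }
    if carpal is not None:
        payload["C_W_mm"] = carpal.C_W.tolist()
        payload["styloid_midpoint_mm"] = carpal.S.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def write_curves_csv(curves, path: str | Path) -> None:
    curves.to_frame().to_csv(path, index=False, float_format="%.6g")


def plot_curves(curves, path: str | Path) -> None:
    """Five-panel displacement-vs-flexion plot with confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dofs = [d for d in ("R_X", "R_Y", "T_X", "T_Y", "T_Z") if d in curves.means]
    fig, axes = plt.subplots(len(dofs), 1, figsize=(7, 2.2 * len(dofs)), sharex=True)
    if len(dofs) == 1:
        axes = [axes]
    g = curves.flexion_grid
    for ax, dof in zip(axes, dofs):
        m, hw = curves.means[dof], curves.half_widths[dof]
        ax.plot(g, m, lw=1.2)
        ax.fill_between(g, m - hw, m + hw, alpha=0.3)
        unit_lbl = "deg" if dof.startswith("R") else "mm"
        ax.set_ylabel(f"{dof} [{unit_lbl}]")
        ax.axhline(0.0, color="k", lw=0.5, alpha=0.5)
    axes[-1].set_xlabel("flexion angle [deg]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_screw_csv(screw, path: str | Path) -> None:
    """Per-step screw parameters: time, phi, axis, IHA point, translation."""
    n_steps = screw.phi.size
    df = pd.DataFrame(
        {
            "time_s": screw.times[:-1],
            "phi_deg": np.degrees(screw.phi),
            "n_x": screw.axis[:, 0],
            "n_y": screw.axis[:, 1],
            "n_z": screw.axis[:, 2],
            "A_x_mm": screw.A[:-1, 0],
            "A_y_mm": screw.A[:-1, 1],
            "A_z_mm": screw.A[:-1, 2],
            "d_mm": screw.d,
            "valid": (screw.axis_defined & screw.frame_valid[:-1]).astype(int),
        },
        index=np.arange(n_steps),
    )
    df.to_csv(path, index=False, float_format="%.9g")
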