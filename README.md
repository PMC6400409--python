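# screwkin

Screw-theory analysis of six-degree-of-freedom joint kinematics from
tracked rigid-body motion.

Biological joints that look like hinges rarely are: a "revolute" elbow
can couple its flexion with a small translation along the flexion axis,
turning it into a **screw joint**.  Deciding whether such couplings are
real requires tracking two bones with sub-hundredth-millimetre
precision, extracting the instantaneous helical (screw) axis of their
relative motion, building an anatomical frame around the measured axis,
and decomposing every pose into six displacement components with honest
confidence bands.  `screwkin` implements that full chain for
musculoskeletal researchers and biomechanical engineers, together with a
synthetic generator that emulates the underlying cadaveric experiment
(an in-vitro sheep elbow flexed 0–91° under optical tracking) so every
stage is verifiable by parameter recovery.

## The method in brief

For poses `(R(t_i), O(t_i))` of the moving bone in the fixed-bone frame,
each incremental rotation `R_i = R(t_{i+1}) R(t_i)^T` yields Rodrigues
(unit-quaternion) parameters

    S = ½√(1 + a₁₁ + a₂₂ + a₃₃),  L = (a₃₂ − a₂₃)/4S,
    M = (a₁₃ − a₃₁)/4S,           N = (a₂₁ − a₁₂)/4S,

hence the step angle `φ = 2 arccos S` and axis `n = (L, M, N)/sin(φ/2)`.
Five-point central differences give the velocity `V_i` of the tracked
origin and the angular velocity `ω_i`; the helical-axis point is
`A_i = O_i + (ω_i × V_i)/(ω_i · ω_i)` and the per-step translation along
the axis is `d_i = (O_{i+1} − O_i)·n_{i+1}`.  Averaging over the gesture
gives the mean flexion axis `(n_m, A_m)`, from which the joint frame

    U_Z = n_m,  U_X = (A_m C_S) × n_m / ‖·‖,  U_Y = U_Z × U_X

is built (`C_S`: best-fit humeral-head sphere centre; origin `O_β` on
the axis at the epicondyle midplane).  Displacements in this frame are
factored as a Z-Y-X Tait-Bryan cascade — flexion `R_Z`,
adduction-abduction `R_Y`, internal-external `R_X`, and translations
`T_X, T_Y, T_Z` — gridded on the flexion angle across repeated trials
with Student-t bands `t·s/√n`.  Finally the motion-derived axis is
compared with the axis of the best-fit articular-surface cylinder
(in-plane distance and unsigned angle).

## Worked example

```python
from screwkin import analyze_study, fit_bones
from screwkin.synthetic import default_cluster_geometries, make_study

trials, bones, truth = make_study("fresh", seed=1, n_trials=25)
gf, gm = default_cluster_geometries()
result = analyze_study(trials, gf, gm, fit_bones(bones),
                       reference_pose=truth.reference_pose)

tz = result.curves.means["T_Z"]
print("significant DoFs :", [d for d, s in result.significance.items() if s])
print("T_Z at 0 / 91 deg:", round(tz[0], 3), "/", round(tz[-1], 3), "mm")
print("t critical       :", round(result.curves.t_critical, 3))
print("axis offset      :", round(result.axis_summary["mean_distance_mm"], 2), "mm")
print("axis tilt        :", round(result.axis_summary["mean_angle_deg"], 2), "deg")
```

prints

```
significant DoFs : ['T_Z']
T_Z at 0 / 91 deg: 0.006 / 0.464 mm
t critical       : 2.064
axis offset      : 1.31 mm
axis tilt        : 5.11 deg
```

The study generator plants a screw joint whose medial-lateral
translation ramps from 0.002 mm to 0.457 mm across the 91° gesture, with
marker noise of 0.012 mm; the analysis recovers that profile from the
noisy trajectories, flags **only** the medial-lateral translation as
significant against the measurement uncertainty (the joint behaves as a
screw, not a plain hinge), and recovers the planted 1.31 mm / 5.11°
discrepancy between the articular-surface cylinder axis and the axis the
bones actually rotate about.

## Command line

```sh
screwkin simulate --scenario fresh --seed 1 --out-dir out/sim
screwkin analyze  --in-dir out/sim --out-dir out/analysis
screwkin compare-axes --in-dir out/sim --out out/axes.json
screwkin show-config
```

`simulate` writes TRC/CSV marker trajectories, ascii-PLY surface
patches, a landmarks JSON and the ground truth; `analyze` writes the DoF
curves (CSV + plot), per-step screw parameters, the joint frame, a
flexion→T_Z coupling table for downstream musculoskeletal tools, and a
JSON report.  Two scenarios are built in: `fresh` (intact joint) and
`dry` (no soft tissue: reduced range, reversed non-monotone
medial-lateral translation).

## Layout

| module | contents |
| --- | --- |
| `screwkin.synthetic` | ground truth, screw-motion generator, marker/surface synthesis, named scenarios |
| `screwkin.pose` | Procrustes rigid fits, relative pose series |
| `screwkin.screw` | Rodrigues extraction, five-point stencils, helical-axis points, mean flexion axis |
| `screwkin.fitting` | orthogonal-distance sphere/cylinder fits |
| `screwkin.frames` | anatomical frame, joint origin, carpal centre |
| `screwkin.dof` | Tait-Bryan decomposition, flexion angle, curve aggregation, significance screen |
| `screwkin.axes` | surface-axis vs motion-axis comparison |
| `screwkin.pipeline`, `screwkin.io`, `screwkin.config`, `screwkin.cli` | orchestration, file formats, configuration, CLI |
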