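# Methods

`screwkin` analyses the six-degree-of-freedom kinematics of a
near-revolute anatomical joint — the motivating system is the
flexion-extension of a quadruped (sheep) elbow tracked in vitro — from
two rigid marker clusters and digitized bone surfaces.  This note
documents the model, the estimators, the numerical choices, and what the
synthetic experiment does and does not establish.

## Model

The joint is treated as a **screw joint**: the radius-ulna rotates about
an axis fixed in the humerus while translating along that same axis as a
function of the flexion angle.  Both bones are rigid; the markers are
bone-fixed (no soft-tissue artifact, matching an in-vitro protocol).

Poses map body coordinates to the fixed (humerus) frame,
`x = R x_body + O`, with lengths in mm, times in s, user-facing angles in
degrees and internal angles in radians.

### Screw decomposition

Between consecutive frames the spatial incremental rotation is
`R_i = R(t_{i+1}) R(t_i)^T`.  Its unit-quaternion (Rodrigues) parameters

    S = 1/2 sqrt(1 + a11 + a22 + a33)
    L = (a32 - a23)/4S,  M = (a13 - a31)/4S,  N = (a21 - a12)/4S

give the step angle `phi = 2 arccos(S)` and axis
`n = (L, M, N)/sin(phi/2)`.  Near `phi = pi` (where `S -> 0`) extraction
switches to the largest-diagonal quaternion branch (threshold
`s_min = 1e-4`) and the step is flagged.  Velocities use the five-point
central difference

    V_i = (O_{i-2} - 8 O_{i-1} + 8 O_{i+1} - O_{i+2}) / (12 dt)

applied to the moving-frame origin; the angular velocity applies the same
stencil to the unwrapped axis-angle rotation vector of the cumulative
orientation.  A scalar-angle variant (differentiating the step-angle
sequence and directing it along the local axis) is available via
`angular_rate_mode="scalar"`; the two agree identically for fixed-axis
motion and the vector form is the default because the helical-axis point

    A_i = O_i + (omega_i x V_i) / (omega_i . omega_i)

requires a vector angular velocity.  The per-step translation along the
axis is `d_i = (O_{i+1} - O_i) . n_{i+1}` (the next step's axis, as the
decomposition defines it; choosing `n_i` instead changes results only at
O(dt)).

### Mean flexion axis

Two estimators are provided:

* **hemisphere** — flip every step axis into a common hemisphere against
  a running reference and average unweighted; the location is the plain
  mean of valid `A_i`.  Appropriate when step angles are well above the
  orientation noise.
* **telescoping** (default) — `n_m = normalize(sum_i phi_i n_i)` over
  the signed step rotation vectors.  Consecutive increments share their
  endpoint orientations, so the sum telescopes to (approximately) the
  total rotation vector: the direction error is set by the two endpoint
  poses, not by the noisiest small steps.  The location is the
  `|omega|^2`-weighted (inverse-variance) mean of valid `A_i`.

The distinction matters because the emulated gesture is slow (91 degrees
over 40 s, peak 3.4 deg/s at 100 Hz).  At that rate the per-step
rotation (~6e-4 rad) is comparable to the cluster orientation noise, so
hemisphere rectification turns sign noise into a large direction bias,
and the stencil-differentiated `omega` sits near unit signal-to-noise,
which both inflates and biases per-step `A_i` (noisy `omega` appears in
the denominator).

For the pipeline, `estimate_mean_axis` additionally (a) applies the
stencil on a decimated pose series (~24 frames across the gesture),
matching the differentiation timescale to the motion, and (b) runs a
second pass tracking the body point nearest the first-pass axis — the
helical-axis point error scales with (lever arm x noise)/omega, and for
a screw joint a body point on the axis stays on the axis.  The
extraction formulas themselves are unchanged.  On noiseless input the
estimate coincides with the single-pass result to numerical precision;
under the study noise it locates the axis to ~0.01 mm and ~0.02 degrees
per trial.

### Anatomical frame and displacement components

With `C_S` the best-fit humeral-head sphere centre, `A_m`/`n_m` the mean
axis, and `E` the epicondyle midpoint:

    U_Z = n_m
    U_X = (A_m C_S) x n_m / || (A_m C_S) x n_m ||
    U_Y = U_Z x U_X
    O_beta = A_m + ((E - A_m) . n_m) n_m

The carpal centre `C_W` is the distal-radius (carpal) trochlea cylinder
axis intersected with the plane normal to it through the styloid
midpoint; the flexion angle is the signed in-plane angle of the
projected `O_beta -> C_W` vector about `+U_Z`, zeroed at the reference
(maximum-extension) pose by default (a configurable fixed zero direction
is supported).  A limb-side switch orients `n_m` so that `+U_Z` points
medially and flexion is a positive rotation.

Displacements relative to the reference pose are expressed about
`O_beta` on `(U_X, U_Y, U_Z)` and factored as the intrinsic Z-Y-X
Tait-Bryan cascade `R = Rot_Z(R_Z) Rot_Y(R_Y) Rot_X(R_X)`, so the first
extracted angle is flexion; samples with `|R_Y|` within 0.1 degrees of
the gimbal singularity are flagged.  Measuring translations about
`O_beta` (rather than the marker-cluster origin) makes a pure rotation
about the joint axis read as zero translation, which is what the T_X/T_Y
"null channels" of a screw joint require.

### Curves, bands and significance

Trials are parameterized by the instantaneous flexion angle (actuation
speed varies across trials), linearly interpolated onto a 1-degree grid,
and averaged; confidence half-widths are `t_{1-alpha/2, n-1} s/sqrt(n)`
(two-tailed, `alpha = 0.05`; with the study's 25 pooled measurements
`t = 2.064`).  Grid points outside a trial's flexion range exclude that
trial there, with counts reported and per-point degrees of freedom
adjusted.  The anatomical frame is rebuilt per trial — the underlying
experiment pools five specimens times five gestures, so frames
necessarily differ — which keeps frame-construction error inside the
across-trial scatter that the bands report.

A displacement channel is **significant** when
`max_grid(|mean| - half_width)` exceeds its measurement uncertainty:
0.012 mm for translations (the tracking uncertainty) and, since no
angular uncertainty is printed for rotations, the noise-propagated
angular equivalent `sqrt(2) sigma / rho` over the cluster RMS radius
`rho` (~0.033 degrees for the defaults).  Flexion itself, the driven
motion, is not screened.

### Surface primitives and axis comparison

Sphere and cylinder fits minimize orthogonal distance
(`||p - c|| - r` and `dist(p, axis) - r`), initialized algebraically
(Kasa) with the cylinder direction seeded from all three covariance
eigenvectors (best algebraic score kept), refined by Levenberg-Marquardt
to 1e-14 relative tolerance.  Axis sign is canonicalized
(largest-magnitude component positive) and the axis point is the
projection of the point centroid onto the axis.  Patches subtending less
than 30 degrees of arc are flagged as weakly constrained.

The surface-fit flexion axis (humeral-trochlea cylinder) is compared to
the motion-derived axis in the `U_X U_Y` plane through `O_beta`:
distance `||P_cyl - O_beta||` (cylinder-axis/plane intersection) and
unsigned angle `arccos(|u_cyl . n_m|)`.  Across specimens, means carry
Student-t half-widths.

## Synthetic experiment

The generator emulates the cadaveric protocol: two rigid four-marker
tetrahedral clusters (~28 mm RMS radius), i.i.d. isotropic Gaussian
marker noise of 0.012 mm per coordinate (the tracking system's maximum
uncertainty; only a scalar is reported, hence the isotropic choice), a
C1 smoothstep flexion ramp 0-91 degrees over 40 s at 100 Hz (the source
experiment states only range and duration of the manual actuation), and
bone patches (sphere cap, two cylinder patches) with 0.02 mm scanner
noise.  Scenario profiles:

* **fresh** — medial-lateral translation rising smoothly from 0.002 mm
  at 0 degrees to 0.457 mm at 91 degrees (the 0.002 mm at zero flexion
  is a load-induced offset: the displacement reference is the unloaded
  zero-flexion pose, which the generator exports with the ground truth);
  all other non-flexion channels zero.
* **dry** — reduced range (0-70 degrees; the source does not print the
  dry range, 70 degrees is this package's assumption), a non-monotone
  medial-lateral profile spanning -0.81 to -0.017 mm built from a
  monotone-segment (PCHIP) interpolant through four knots (exact curve
  shapes are not published; only the endpoint ranges are matched), and
  tens-of-millidegree adduction-abduction / internal-external
  perturbations matched to the printed ranges.

The humeral-trochlea cylinder is planted at a known in-plane offset
(1.31 mm) and tilt (5.11 degrees) from the true motion axis so the axis
comparison is verifiable by recovery.

What the synthetic data does **not** emulate: cartilage deformation
under load, soft-tissue artifact, marker dropout, non-Gaussian or
spatially correlated measurement error, camera geometry, and
inter-specimen anatomical variability (trials differ only in noise
realizations).  Passing recovery tests therefore demonstrates the
correctness and noise behaviour of the estimators under the stated
error model, not robustness to those unmodelled effects.

## Numerical choices

* Rotation extraction clamps `arccos` arguments to [-1, 1]; the internal
  rotation-vector conversion uses `phi = 2 atan2(||(L,M,N)||, S)`, which
  keeps full precision at small angles where `2 arccos(S)` loses half
  its digits (the public `axis_angle` keeps the closed-form arccos).
* Validity thresholds: `phi_min = 1e-6` rad per step (axis direction
  undefined below), `omega_min = 1e-8` rad/s (helical-axis point
  undefined below).  Invalid steps are flagged and excluded from means,
  never silently dropped; the first and last two frames carry no stencil
  support and are likewise excluded.
* The rigid (Procrustes) fit corrects reflections via the
  smallest-singular-value sign; collinear clusters are an error.
* Missing marker frames are an error, not interpolated.
* No smoothing or filtering is applied to trajectories beyond the
  five-point stencil itself.

## Problem sizes

Default study conditions are used throughout the tests and the
acceptance script: 4001 frames per trial, 25 trials per study, 2000
points per surface patch, 20 replicate studies for the end-to-end
recovery check, and 1000 replicates for the confidence-band coverage
simulation (run on directly synthesized Gaussian trial curves, where
per-point coverage is exactly the nominal 95%).

## Known limitations

* The mean-axis location estimator assumes a dominantly fixed-axis
  gesture; strongly non-screw motion would need a time-resolved axis.
* The dry scenario's small rotational perturbations make the "mean
  flexion axis" an approximation; noiseless recovery of the planted dry
  profiles is good to ~5e-3 degrees rather than machine precision.
* Euler-angle output is undefined within 0.1 degrees of the Z-Y-X
  gimbal singularity (flagged, not repaired); irrelevant for elbow-like
  ranges.
* PLY surface files are written in 32-bit ascii (~1e-5 mm quantization
  at anatomical scale), far below scanner noise but visible next to
  machine-precision in-memory results.
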