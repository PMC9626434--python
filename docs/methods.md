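# Methods

This note documents the models, numerical choices and limitations behind
`shoulderkin`. It describes *how* quantities are computed; every number
quoted as behaviour (residual magnitudes, monotonicity, coverage) is one
the test suite or `scripts/acceptance.py` computes at run time.

## Kinematic chain

The shoulder is modelled as four rigid segments — thorax, clavicle,
scapula, humerus — connected in a serial chain by three rotational
joints: the sternoclavicular joint (SCJ) as a 2-DOF universal joint
(rotations about the parent Y then X axes), and the acromioclavicular
(ACJ) and glenohumeral (GHJ) joints as 3-DOF ball joints (Y, X, Z). The
eight generalized coordinates, in degrees, are

```
q = (scj_y, scj_x, acj_y, acj_x, acj_z, ghj_y, ghj_x, ghj_z)
```

Segment frames follow the ISB conventions: thorax origin IJ with Y
cranial from the sternum/spine midpoints; clavicle origin SC with Z
along SC→AC; scapula origin AA with Z along TS→AA and X perpendicular to
the AA–AI–TS plane pointing forward; humerus origin at the GHJ centre
with Y from the elbow centre (midpoint of EL and EM) toward GH. All
frames are right-handed; world is Y-up, X-anterior, Z-right; models are
of a right shoulder.

Each joint stores its centre in *both* adjacent segment frames plus a
constant **rest rotation** — the child's orientation relative to the
parent at the assembly posture. Poses compose as

```
T(centre_in_parent) · R(q_joint) · R_rest · T(−centre_in_child)
```

so (a) the two sides of every joint coincide exactly for any q (joint
congruency holds at machine precision, no distraction or
co-penetration), (b) q = 0 reproduces the posture the model was
assembled in, and (c) the generalized rotations act about the
parent-frame joint axes, matching the convention that GHJ angles are a
YXZ Cardan decomposition in the scapular frame. For the synthetic
template below the rest rotations are exactly the identity, so IK
coordinates, DirectK Cardan angles and programmed angles live on the
same scale.

Joint centres: SCJ at the SC landmark, ACJ at AC (the joints articulate
at these landmarks and no offset convention is imposed), GHJ at a supplied
centre — in practice a humeral-head sphere fit or the functional SCoRE
estimate. The elbow centre is the EL/EM midpoint (standard ISB usage;
"the elbow joint" is otherwise undefined).

## Model personalisation

**Image-based route** (`assemble_model`): segment frames are built from
the participant's own landmarks; local landmark/marker coordinates,
joint centres and rest rotations are derived directly. In the in-silico
study the generator's truth anatomy plays this role.

**Scaled-generic route** (`scale_generic`): a generic template is scaled
to the participant's measurements —

- clavicle and humerus isotropically, by the SCJ→ACJ and GHJ→elbow
  distance ratios (so those inter-joint distances match the target
  exactly);
- scapula anisotropically: a factor along the scapular Z (spine)
  direction and a uniform factor in the X–Y plane, solved from the 2×2
  linear system that makes the scaled AC–TS *and* AI–TS distances equal
  the target measurements exactly. When the template's AC–TS span is
  purely along Z and AI–TS purely in-plane this reduces to the two
  plain distance ratios;
- thorax by three directional ratios measured in the thorax frame:
  anteroposterior from the IJ–C7 span, vertical from the
  mid(IJ,C7)–mid(PX,T8) span, mediolateral from the Z-projection of
  IJ–SC. The width is taken at SC — the clavicle's root on the thorax —
  because that is the thorax dimension the kinematic chain actually
  feels; measuring it at AC would confound thorax width with clavicle
  length and breaks the exactness of the degenerate (zero-error)
  reconstruction.

Joint centres of the scaled model are re-derived from the scaled
geometry (which three directions the original protocol scaled, and
whether centres were re-derived, is not documented; these are this
package's choices).

**Anatomical errors** are the signed differences (model A minus model B)
of the three inter-joint distances, reported in centimetres to match the
regression's °/cm coefficient units.

## Inverse kinematics

Per frame, the thorax pose is fixed first by least-squares rigid
registration (Kabsch/orthogonal Procrustes with SVD and reflection
correction) of the four thorax markers; then the 8 joint coordinates
minimize the weighted squared marker error over the remaining markers
(unit weights by default) by Levenberg–Marquardt (scipy `least_squares`,
method `lm`, xtol 1e-10, ftol 1e-12, ≤ 100 iterations' worth of
evaluations), warm-started from the previous frame (frame 0 from
anatomical neutral q = 0 — all tasks start near neutral). An option
co-optimizes a 6-DOF thorax correction with the joint coordinates.
Angles are radians internally, degrees at every API boundary, wrapped to
(−180°, 180°]. Warm-start values below 1e-9 rad are snapped to zero so
MINPACK's |x|-relative finite-difference step never degenerates.

The reported global RMSd pools squared weighted marker residuals over
all valid frames and markers (thorax markers included); 2.5 cm is an
acceptance threshold — exceeding it logs a warning, it does not fail the
solve. Frames whose markers cannot constrain the chain (fewer than 3
finite thorax markers, or no distal markers) are flagged and excluded
from pooling.

On noiseless data generated by the same model the solve is exact to
numerical precision (programmed-angle recovery ≤ 1e-3°, residual
≈ 1e-16 m), which the round-trip tests assert.

## DirectK

The scapula pose comes from rigid registration of the ≥3 cluster
markers against their calibration positions; the wand-calibrated
scapular landmarks (AA, TS, AI) and the GHJ centre are reconstructed
from that pose; ISB scapula and humerus frames are rebuilt per frame and
the GHJ rotation (scapulaᵀ·humerus) is decomposed with the YXZ Cardan
sequence. The AC marker is not used by DirectK (it belongs to the
clavicle for model work). Frames with missing required markers are
flagged and set to NaN, not interpolated.

Gimbal lock is declared when the critical cosine falls below 1e-8; the
third angle is zeroed, the first absorbs the free sum, and the frame is
flagged — reported, never repaired. The YX′Y′′ Euler extraction is
provided for comparison; it flags exactly the near-0°/180° second-angle
configurations where the ISB sequence degenerates while YXZ does not.

**SCoRE**: the functional joint centre is the point stationary in two
segment frames, solved from the stacked linear system
`R_parent·c_p − R_child·c_c = t_child − t_parent` over all frames by
least squares; rank deficiency (insufficient relative rotation) is an
error. **Sphere fit**: algebraic (Coope) linear fit seeding a
Gauss–Newton refinement of `‖p − c‖ − r`; ≥5 non-coplanar points
required.

## Signal conditioning

Marker trajectories are low-pass filtered before any kinematics
(second-order Butterworth designed at 4 Hz for 200 Hz data, applied
forward-backward for zero lag; filtering angles instead is available but
off by default). Task time is normalized to [0, 1] with each of the
three phases mapped linearly onto one third of the axis — a
piecewise-linear time warp with linear interpolation onto a 100-point
grid (99 steps + endpoint, so the phase boundaries land exactly on
sample 33 and 66). ROM is max − min of the named angle; trial summaries
use the sample SD across the six repetitions.

## Agreement statistics

Bland–Altman: differences a − b pooled one-per-normalized-time-point per
repetition (per-repetition summaries available); bias = mean, limits of
agreement = bias ± 2·SD (the multiplier is exactly 2, configurable, not
1.96). For normal differences the inside-LOA fraction approaches
Φ(2) − Φ(−2) ≈ 0.9545; for heavy-tailed (t₃) differences the sample SD
is tail-inflated and coverage is *higher* (≈ 0.959 in closed form) — a
caution against reading the LOA as exact 95% bounds off-normality.

The ΔROM regression is ordinary least squares with intercept and the
five predictors (sex 1/1.1 kept verbatim — an unusual coding retained
for comparability, 0/1 available; BMI kg/m²; three errors in cm). The
model p-value is the overall F-test of the slopes. Rank-deficient
designs raise an error naming the dependent columns. Fitting needs
n ≥ 7 rows (5 predictors + intercept + 1).

## Synthetic study generator

The generator defines the in-silico study conditions:

- **Anatomy**: a neutral-posture landmark template constructed so all
  four ISB frames coincide with the world frame (arm hanging, right
  shoulder). Reference lengths at the cohort-mean stature: clavicle
  0.15 m, ACJ–GHJ 0.04 m, humerus 0.30 m, scaled with height and given
  a seeded ±2% shape jitter, clipped to plausible ranges (clavicle
  0.12–0.18 m, humerus 0.26–0.36 m). Cohort anthropometrics mirror the
  study population: 8 F / 4 M, height 167.0 ± 7.9 cm, mass
  60.0 ± 11.4 kg.
- **Tasks**: three phases of 2 s at 200 Hz (1200 frames; boundaries at
  400 and 800), minimum-jerk ramps, hold at peak. `peak` is the driven
  GHJ coordinate's peak; the default AA/FE programs use 60° with a
  scapulohumeral rhythm adding a scapulothoracic share of 0.5× the
  glenohumeral one (split 2:1 ACJ:SCJ for AA, carried by the ACJ for
  FE) about the same world axis, so the contributions add exactly and
  peak thoraco-humeral elevation is exactly 90° — shoulder level, with
  the classic 2:1 glenohumeral:scapulothoracic ratio. IER ramps the
  axial rotation from −40° (external) to +40° with no rhythm.
- **Markers**: the 10-marker experimental set (C7, T8, IJ, PX thorax;
  AC; a 3-marker scapular-spine cluster with offsets proportional to
  the spine length; EL, EM). Measurement noise is isotropic Gaussian
  (default SD 5 mm); the skin-motion artifact is a rigid offset of the
  cluster of amplitude × sin(elevation) along the scapular anterior
  axis (default 5 mm) — deliberately a direction-level emulation of
  elevation-dependent skin sliding, not a physiological model.
  Repeated trials differ only in the noise seed; everything is
  reproducible bit-for-bit under a fixed seed.
- **Error injection**: the scaled-generic counterpart is built by
  scaling the fixed template (itself the cohort-mean synthetic anatomy —
  nothing third-party) to the participant's landmarks, then rescaling
  the three segment lengths so the anatomical errors equal the
  prescribed (Δclavicle, Δscapula, Δhumerus) exactly. Error draws
  default to Normal(0, 1 cm) truncated at ±3 cm — the real study never
  published its measured Δ values, so these magnitudes are an explicit
  assumption surfaced in the configuration.
- **Cohorts**: `linear` mode draws ΔROM from the regression equation
  with chosen coefficients plus Gaussian noise (for fast parameter
  recovery); `mechanistic` mode computes ΔROM by actually running both
  models through IK on synthesized trials.

What passing tests on this generator do **not** show about real data:
the artifact model is simplistic, marker placement is error-free,
anatomies are template-shaped rather than truly morphologically diverse,
and the truth model is exactly realizable by the IK chain — so absolute
agreement numbers are optimistic; the *propagation structure* (which
errors matter, in which direction, and how statistics behave) is what
transfers.

## Problem sizes

Full-rate trials are 1200 frames; IK is solved on a strided grid (every
20th–60th frame depending on the analysis) and compared on that grid —
the motions are band-limited at 4 Hz so the strided solution loses no
information relevant to ROM or trace comparisons. The cohort replica
(12 × 3 × 6 trials) runs in a few minutes on one CPU at stride 60; the
acceptance script pools 4320 solved frames for its residual statistic.

## Known limitations

- Kinematics only: no inertia, muscles, or dynamics downstream.
- No automatic phase detection or marker gap filling; phases come from
  the generator or an events sidecar, dropout frames are flagged.
- The thorax-direction and scapula-axis assignments of the scaling
  protocol are this package's explicit choices where the original
  protocol is silent; alternatives would change Δ magnitudes but not
  the analysis machinery.
- Single (right) shoulder; no left-side mirroring.
- The mechanistic cohort at n = 12 rarely reaches regression
  significance — as expected at that sample size; the linear mode
  exists precisely to validate the statistical layer at scale.
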