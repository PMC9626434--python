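# shoulderkin

Multi-body shoulder kinematics: how anatomical (segment-length) errors,
sex and BMI propagate into glenohumeral joint angles.

## The problem

Shoulder kinematics can be computed two ways from optical motion capture:
directly, by building ISB segment coordinate systems from marker positions
frame by frame (**DirectK**), or through **inverse kinematics (IK)** with a
rigid multi-body model, which finds the joint coordinates minimizing the
global marker error at every frame and enforces joint congruency. The IK
result depends on the model's anatomy. Personalised models built from
medical images carry millimetre-accurate segment geometry; the common
alternative — linearly scaling a generic template to a participant's
measurements — introduces *anatomical errors*: differences in the
inter-joint distances

- Δ‖Clavicle‖ — sternoclavicular (SCJ) to acromioclavicular (ACJ) joint,
- Δ‖Scapula‖ — ACJ to glenohumeral joint (GHJ),
- Δ‖Humerus‖ — GHJ to the elbow centre (midpoint of the epicondyles),

which propagate into the computed joint angles. This package implements
the full analysis chain for quantifying that propagation on a
**4-segment (thorax–clavicle–scapula–humerus), 8-DOF** shoulder model
(SCJ universal 2-DOF; ACJ and GHJ ball 3-DOF), for three planar tasks —
abduction/adduction (AA), flexion/extension (FE), internal/external
rotation (IER) — each executed in three 2-s phases (ramp to shoulder
level / hold / return) at 200 Hz.

GHJ angles use the **YXZ Cardan sequence** (plane-of-elevation-free
decomposition `R = Ry(α)·Rx(β)·Rz(γ)` of the humerus orientation relative
to the scapula), which avoids the gimbal lock the ISB YX′Y′′ Euler
sequence suffers near 0° and 90° of abduction. Agreement between methods
is summarized with **Bland–Altman** statistics (bias and limits of
agreement = bias ± 2·SD of the paired differences), and the
range-of-motion difference between model types is explained by the
multi-linear regression

```
ΔROM = intercept + β1·Sex + β2·BMI + β3·Δ‖Clavicle‖ + β4·Δ‖Scapula‖ + β5·Δ‖Humerus‖
```

with sex coded 1 (male) / 1.1 (female), BMI in kg/m², errors in cm; a
model counts as significant at p ≤ 0.05 and a predictor at |t| ≥ 2.

Since no motion-capture/MRI cohort is shipped, a first-class synthetic
generator (`shoulderkin.synth`) produces everything the study design
needs: per-participant anatomies, task joint-angle programs with a 2:1
glenohumeral:scapulothoracic rhythm, 200 Hz marker trajectories with
Gaussian noise and an elevation-dependent scapular skin artifact, and
scaled-generic counterpart models carrying *controlled* anatomical
errors.

## Worked example

```python
import numpy as np
from shoulderkin import anatomical_errors, ik_solve_trajectory, rmsd_between
from shoulderkin.synth import (AnatomyParams, TaskProgram, generate_anatomy,
                               generate_task, make_scaled_generic,
                               synthesize_markers)

# a participant's anatomy ("MRI-based" truth) and a scaled-generic model
# carrying +0.5 / +1.0 / -1.5 cm inter-joint-distance errors
landmarks, gh, truth = generate_anatomy(AnatomyParams(height_cm=167), seed=1)
sg = make_scaled_generic(truth, (0.5, 1.0, -1.5))
print(anatomical_errors(truth, sg))

# one noiseless abduction trial, solved with both models
q, phases = generate_task(TaskProgram("AA"))
markers = synthesize_markers(truth, q, phases, noise=None)
res_truth = ik_solve_trajectory(truth, markers, stride=20)
res_sg = ik_solve_trajectory(sg, markers, stride=20)
ghj_t = res_truth.ghj_cardan(truth)   # (frames, 3): y, x, z in degrees
ghj_s = res_sg.ghj_cardan(sg)
print(f"abduction RMSd between models: {rmsd_between(ghj_t[:,1], ghj_s[:,1]):.2f} deg")
print(f"IK marker residual (SG): {1e3*res_sg.global_rmsd:.1f} mm")
```

prints

```
AnatomicalErrors(delta_clavicle=0.5000000000000004, delta_scapula=1.0000000000000002, delta_humerus=-1.5000000000000013)
abduction RMSd between models: 5.16 deg
IK marker residual (SG): 4.8 mm
```

— the truth model reproduces the programmed motion exactly while the
error-injected scaled-generic model deviates by several degrees in the
main angle, with a marker residual well inside the 2.5 cm tolerance.

The `analysis/` scripts run the study replica end to end:
`01_simulate_study.py` (materialize sample inputs: TRC trials, landmark
JSON, event sidecars), `02_trial_kinematics.py` (DirectK vs IK per
trial), `03_cohort_agreement.py` (12 participants × 3 tasks × 6 trials;
between-model RMSd, Bland–Altman against DirectK),
`04_rom_regression.py` (ΔROM regression tables). Compact tables land
under `results/`, bulky regenerable intermediates under `scratch/`.

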