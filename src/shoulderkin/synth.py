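"""Synthetic study generator: anatomies, task programs, marker trajectories
and cohorts.

Everything the real study measured is emulated so the pipeline can be
exercised end to end without external data: per-participant bony
anatomies (truth models standing in for the image-based route),
scaled-generic counterparts carrying controlled inter-joint-distance
errors, 200 Hz marker trajectories of the three planar tasks (three 2-s
phases each) with additive measurement noise and an elevation-dependent
scapular skin-motion artifact, and cohort tables with anthropometrics for
the ΔROM regression.

The landmark template is constructed so that all four segment ISB frames
coincide with the world frame at the neutral posture (arm along the
thorax): joint rest rotations are then identity, and programmed joint
angles, IK coordinates and DirectK Cardan angles are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anatomy import (
    AnatomicalErrors,
    LandmarkSet,
    ShoulderModel,
    assemble_model,
    scale_generic,
)
from .directk import MarkerTrajectorySet
from .exceptions import ValidationError
from .ik import _FKEngine, thoracohumeral_elevation
from .signal_prep import PhaseAnnotation

__all__ = [
    "AnatomyParams",
    "TaskProgram",
    "NoiseModel",
    "generate_anatomy",
    "default_template",
    "generate_task",
    "synthesize_markers",
    "make_scaled_generic",
    "generate_cohort",
    "COHORT_MEAN_HEIGHT_CM",
    "COHORT_MEAN_MASS_KG",
]

# study-cohort anthropometrics the generator emulates (mean ± SD)
COHORT_MEAN_HEIGHT_CM = 167.0
COHORT_SD_HEIGHT_CM = 7.9
COHORT_MEAN_MASS_KG = 60.0
COHORT_SD_MASS_KG = 11.4
COHORT_FEMALE_FRACTION = 8.0 / 12.0

# reference segment lengths at the cohort-mean stature (m)
_REF_CLAVICLE = 0.15
_REF_SCAPULA = 0.04   # ACJ to GHJ
_REF_HUMERUS = 0.30   # GHJ to elbow centre


@dataclass(frozen=True)
class AnatomyParams:
    """Anthropometrics and segment lengths of one synthetic participant.

    Segment lengths default to the reference values scaled by stature.
    Plausibility ranges are enforced: clavicle 0.12–0.18 m, humerus
    0.26–0.36 m.
    """

    sex_code: float = 1.0          # 1 male, 1.1 female
    height_cm: float = COHORT_MEAN_HEIGHT_CM
    mass_kg: float = COHORT_MEAN_MASS_KG
    clavicle_length: float | None = None
    scapula_length: float | None = None
    humerus_length: float | None = None

    def __post_init__(self):
        if self.sex_code not in (1.0, 1.1):
            raise ValidationError("sex_code must be 1 (male) or 1.1 (female)")
        if not (120.0 < self.height_cm < 220.0):
            raise ValidationError(f"implausible height: {self.height_cm} cm")
        if not (30.0 < self.mass_kg < 180.0):
            raise ValidationError(f"implausible mass: {self.mass_kg} kg")

    @property
    def bmi(self) -> float:
        return self.mass_kg / (self.height_cm / 100.0) ** 2

    def resolved_lengths(self) -> tuple[float, float, float]:
        s = self.height_cm / COHORT_MEAN_HEIGHT_CM
        clav = self.clavicle_length if self.clavicle_length is not None else _REF_CLAVICLE * s
        scap = self.scapula_length if self.scapula_length is not None else _REF_SCAPULA * s
        hum = self.humerus_length if self.humerus_length is not None else _REF_HUMERUS * s
        if not (0.12 <= clav <= 0.18):
            raise ValidationError(f"clavicle length {clav:.3f} m outside 0.12-0.18 m")
        if not (0.26 <= hum <= 0.36):
            raise ValidationError(f"humerus length {hum:.3f} m outside 0.26-0.36 m")
        if not (0.02 <= scap <= 0.08):
            raise ValidationError(f"scapula (ACJ-GHJ) length {scap:.3f} m outside 0.02-0.08 m")
        return clav, scap, hum


def _template_landmarks(clav: float, scap: float, hum: float,
                        thorax_scale=(1.0, 1.0, 1.0)) -> tuple[LandmarkSet, np.ndarray]:
    """World landmarks of the aligned neutral-posture template.

    Right shoulder; world X anterior, Y up, Z right; arm hanging along the
    thorax. Constructed so every segment's ISB frame equals the world frame.
    """
    sx, sy, sz = thorax_scale
    t = np.array([sx, sy, sz])
    lm = LandmarkSet()
    lm["IJ"] = t * np.array([0.0, 0.0, 0.0])
    lm["C7"] = t * np.array([-0.10, 0.0, 0.0])
    lm["PX"] = t * np.array([0.0, -0.15, 0.0])
    lm["T8"] = t * np.array([-0.10, -0.15, 0.0])
    lm["SC"] = t * np.array([0.0, 0.0, 0.02])
    ac = lm["SC"] + np.array([0.0, 0.0, clav])
    lm["AC"] = ac
    f = scap / _REF_SCAPULA
    lm["AA"] = ac + f * np.array([-0.010, -0.005, 0.0])
    lm["TS"] = ac + f * np.array([-0.010, -0.005, -0.11])
    lm["AI"] = ac + f * np.array([-0.010, -0.125, -0.10])
    lm["PC"] = ac + f * np.array([0.020, -0.020, -0.01])
    gh = ac + np.array([0.0, -scap, 0.0])
    elbow = gh + np.array([0.0, -hum, 0.0])
    fh = hum / _REF_HUMERUS
    lm["EL"] = elbow + np.array([0.0, 0.0, 0.02 * fh])
    lm["EM"] = elbow + np.array([0.0, 0.0, -0.02 * fh])
    return lm, gh


def generate_anatomy(params: AnatomyParams, seed: int = 0,
                     shape_jitter_sd: float = 0.02):
    """Deterministic participant anatomy: ``(landmarks, gh_centre, model)``.

    Segment lengths follow stature with a seeded multiplicative jitter of
    relative SD ``shape_jitter_sd`` (clipped to the plausible ranges), so a
    cohort shows anatomical variability beyond pure stature scaling. The
    returned model has provenance ``synthetic_truth``.
    """
    rng = np.random.default_rng(seed)
    jit = np.clip(rng.normal(1.0, shape_jitter_sd, size=4), 0.9, 1.1)
    clav0, scap0, hum0 = params.resolved_lengths()
    clav = float(np.clip(clav0 * jit[0], 0.12, 0.18))
    scap = float(np.clip(scap0 * jit[1], 0.02, 0.08))
    hum = float(np.clip(hum0 * jit[2], 0.26, 0.36))
    s = params.height_cm / COHORT_MEAN_HEIGHT_CM
    thorax_scale = (s, s, float(s * jit[3]))
    landmarks, gh = _template_landmarks(clav, scap, hum, thorax_scale)
    model = assemble_model(landmarks, gh, provenance="synthetic_truth")
    return landmarks, gh, model


def default_template() -> ShoulderModel:
    """The fixed generic template: a synthetic anatomy at the cohort mean.

    Serves as the scaling source for every scaled-generic model; no
    third-party model geometry is involved.
    """
    landmarks, gh = _template_landmarks(_REF_CLAVICLE, _REF_SCAPULA, _REF_HUMERUS)
    return assemble_model(landmarks, gh, provenance="synthetic_truth")


# ---------------------------------------------------------------------------
# task programs


_DEFAULT_PEAK = {"AA": 60.0, "FE": 60.0, "IER": 40.0}
_DEFAULT_ST_RATIO = {"AA": 0.5, "FE": 0.5, "IER": 0.0}


@dataclass(frozen=True)
class TaskProgram:
    """Joint-angle program of one planar task.

    Three consecutive phases (ramp up, hold, ramp down), each of
    ``phase_duration`` seconds, sampled at ``rate`` Hz with a minimum-jerk
    ramp profile. ``peak`` is the peak excursion of the driven GHJ
    coordinate (abduction about X for AA, flexion about Z for FE, axial
    rotation about Y for IER, which ramps from −peak external to +peak
    internal). ``st_to_gh_ratio`` adds a scapulohumeral rhythm: the
    scapulothoracic contribution (via SCJ/ACJ angles about the same world
    axis) as a fraction of the glenohumeral one. The defaults (peak 60°,
    ratio 0.5 for AA/FE) raise the arm to 90° of thoraco-humeral elevation
    — shoulder level — with the classic 2:1 glenohumeral:scapulothoracic
    share.
    """

    task: str
    phase_duration: float = 2.0
    peak: float | None = None
    rate: float = 200.0
    st_to_gh_ratio: float | None = None

    def __post_init__(self):
        if self.task not in ("AA", "FE", "IER"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.phase_duration <= 0 or self.rate <= 0:
            raise ValidationError("phase_duration and rate must be positive")

    @property
    def resolved_peak(self) -> float:
        return _DEFAULT_PEAK[self.task] if self.peak is None else float(self.peak)

    @property
    def resolved_st_ratio(self) -> float:
        if self.st_to_gh_ratio is None:
            return _DEFAULT_ST_RATIO[self.task]
        return float(self.st_to_gh_ratio)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10.0 * tau ** 3 - 15.0 * tau ** 4 + 6.0 * tau ** 5


def generate_task(program: TaskProgram) -> tuple[np.ndarray, PhaseAnnotation]:
    """Generalized-coordinate trajectory (frames × 8, degrees) + phases.

    Phase 1 ramps the driven angle from its start to the peak with a
    minimum-jerk profile, phase 2 holds the peak, phase 3 ramps back.
    """
    n_p = int(round(program.phase_duration * program.rate))
    if n_p < 2:
        raise ValidationError("phase too short for the sampling rate")
    i = np.arange(n_p)
    up = _min_jerk(i / n_p)            # reaches 1 at the phase-2 boundary
    down = 1.0 - _min_jerk((i + 1) / n_p)
    prof = np.concatenate([up, np.ones(n_p), down])
    F = 3 * n_p
    q = np.zeros((F, 8))
    peak = program.resolved_peak
    r = program.resolved_st_ratio
    if program.task == "AA":
        q[:, 6] = peak * prof                      # ghj_x: abduction
        q[:, 3] = peak * r * (2.0 / 3.0) * prof    # acj_x
        q[:, 1] = peak * r * (1.0 / 3.0) * prof    # scj_x
    elif program.task == "FE":
        q[:, 7] = -peak * prof                     # ghj_z: flexion (arm forward)
        q[:, 4] = -peak * r * prof                 # acj_z carries the ST share
    else:  # IER: maximal external rotation -> internal, then back
        q[:, 5] = -peak + 2.0 * peak * prof        # ghj_y
    phases = PhaseAnnotation(((0, n_p), (n_p, 2 * n_p), (2 * n_p, 3 * n_p)))
    return q, phases


# ---------------------------------------------------------------------------
# marker synthesis


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections added to synthetic markers.

    ``marker_sd`` is isotropic additive Gaussian noise on every marker
    coordinate; ``artifact_amplitude`` scales an elevation-dependent rigid
    offset of the scapular cluster (amplitude × sin(elevation) along the
    scapular anterior axis), emulating the skin sliding over the scapula
    that grows with arm elevation.
    """

    marker_sd: float = 0.005
    artifact_amplitude: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.marker_sd < 0 or self.artifact_amplitude < 0:
            raise ValidationError("noise magnitudes must be non-negative")


def synthesize_markers(model: ShoulderModel, q_trajectory,
                       phases: PhaseAnnotation | None = None,
                       noise: NoiseModel | None = None,
                       thorax_poses=None, rate: float = 200.0) -> MarkerTrajectorySet:
    """Forward-simulate marker trajectories for a joint-angle program.

    ``thorax_poses`` may be None (thorax fixed at the assembly posture), a
    single pose, or a per-frame sequence of ``(R, o)`` pairs. Noise and the
    scapular artifact are applied per the :class:`NoiseModel`; trials
    differing only in the noise seed emulate repeated task executions.
    """
    q_arr = np.atleast_2d(np.asarray(q_trajectory, dtype=float))
    F = len(q_arr)
    engine = _FKEngine(model)
    names = engine.marker_names
    out = np.empty((F, len(names), 3))
    scap_rows = engine.marker_owner == 2
    amp = 0.0 if noise is None else noise.artifact_amplitude
    elev = thoracohumeral_elevation(model, q_arr) if amp > 0 else None
    for f in range(F):
        if thorax_poses is None:
            Rt, ot = np.eye(3), np.zeros(3)
        elif hasattr(thorax_poses, "axes"):
            Rt, ot = thorax_poses.axes, thorax_poses.origin
        else:
            Rt, ot = thorax_poses[f]
        poses = engine.poses(np.deg2rad(q_arr[f]), Rt, ot)
        pos = np.empty((len(names), 3))
        for k in range(4):
            sel = engine.marker_owner == k
            if np.any(sel):
                R, o = poses[k]
                pos[sel] = engine.locals[sel] @ R.T + o
        if amp > 0:
            R_scap = poses[2][0]
            pos[scap_rows] += amp * np.sin(np.deg2rad(elev[f])) * R_scap[:, 0]
        out[f] = pos
    if noise is not None and noise.marker_sd > 0:
        rng = np.random.default_rng(noise.seed)
        out = out + rng.normal(0.0, noise.marker_sd, size=out.shape)
    events = {}
    if phases is not None:
        events["phases"] = [list(p) for p in phases.phases]
    return MarkerTrajectorySet(labels=names, positions=out, rate=rate, events=events)


# ---------------------------------------------------------------------------
# scaled-generic counterpart with controlled anatomical errors


def _world_landmarks_at_neutral(model: ShoulderModel) -> tuple[LandmarkSet, np.ndarray]:
    """Landmarks and GHJ centre in a thorax-fixed world at q = 0.

    Only distances and segment-frame projections are consumed downstream,
    so the arbitrary (identity) thorax pose is immaterial.
    """
    engine = _FKEngine(model, marker_names=[])
    poses = engine.poses(np.zeros(8), np.eye(3), np.zeros(3))
    order = ("thorax", "clavicle", "scapula", "humerus")
    world = LandmarkSet()
    for k, seg_name in enumerate(order):
        R, o = poses[k]
        for n, p in model.segments[seg_name].local_landmarks.items():
            if n not in world:
                world[n] = R @ p + o
    ghj = model.joint("GHJ")
    R2, o2 = poses[2]
    gh = R2 @ ghj.centre_in_parent + o2
    return world, gh


def _rescale_segment_lengths(model: ShoulderModel, factors: dict) -> ShoulderModel:
    """Isotropically rescale clavicle/scapula/humerus local geometry."""
    from .anatomy import _scale_segment  # shared helper

    f_c = factors.get("clavicle", 1.0)
    f_s = factors.get("scapula", 1.0)
    f_h = factors.get("humerus", 1.0)
    segs = dict(model.segments)
    segs["clavicle"] = _scale_segment(segs["clavicle"], np.full(3, f_c))
    segs["scapula"] = _scale_segment(segs["scapula"], np.full(3, f_s))
    segs["humerus"] = _scale_segment(segs["humerus"], np.full(3, f_h))
    scj, acj, ghj = model.joints
    joints = [
        replace(scj, centre_in_child=scj.centre_in_child * f_c),
        replace(acj, centre_in_parent=acj.centre_in_parent * f_c,
                centre_in_child=acj.centre_in_child * f_s),
        replace(ghj, centre_in_parent=ghj.centre_in_parent * f_s,
                centre_in_child=ghj.centre_in_child * f_h),
    ]
    return ShoulderModel(segments=segs, joints=joints, provenance=model.provenance)


def make_scaled_generic(truth_model: ShoulderModel, error_spec=(0.0, 0.0, 0.0),
                        template: ShoulderModel | None = None) -> ShoulderModel:
    """Scaled-generic counterpart with prescribed anatomical errors.

    The generic template is scaled to the participant's landmark
    measurements (as the study's scaling protocol would), then the three
    segment lengths are adjusted so that
    ``anatomical_errors(truth, result)`` equals ``error_spec`` (cm, signed
    truth-minus-generic) to numerical precision — giving the experimenter
    direct control over the error magnitudes whose propagation is studied.
    """
    if isinstance(error_spec, AnatomicalErrors):
        err = error_spec.as_array()
    else:
        err = np.asarray(error_spec, dtype=float)
        if err.shape != (3,):
            raise ValidationError("error_spec must give (clavicle, scapula, humerus) in cm")
    target_lm, target_gh = _world_landmarks_at_neutral(truth_model)
    sg, _ = scale_generic(template or default_template(), target_lm, target_gh)
    truth_d = truth_model.inter_joint_distances()
    cur_d = sg.inter_joint_distances()
    factors = {}
    for key, e in zip(("clavicle", "scapula", "humerus"), err):
        desired = truth_d[key] - e / 100.0
        if desired <= 1e-4:
            raise ValidationError(
                f"infeasible anatomical error for {key}: resulting length {desired:.4f} m"
            )
        factors[key] = desired / cur_d[key]
    return _rescale_segment_lengths(sg, factors)


# ---------------------------------------------------------------------------
# cohorts


#: generator default for the linear-mode ΔROM coefficients
#: (intercept, sex, BMI, Δclavicle, Δscapula, Δhumerus)
DEFAULT_COEFFICIENTS = (-5.6, 1.3, 0.9, 1.5, 5.0, -8.9)


def _sample_anthropometrics(n: int, rng: np.random.Generator) -> list[AnatomyParams]:
    n_female = int(round(COHORT_FEMALE_FRACTION * n))
    sexes = np.array([1.1] * n_female + [1.0] * (n - n_female))
    rng.shuffle(sexes)
    heights = np.clip(rng.normal(COHORT_MEAN_HEIGHT_CM, COHORT_SD_HEIGHT_CM, n), 150.0, 190.0)
    masses = np.clip(rng.normal(COHORT_MEAN_MASS_KG, COHORT_SD_MASS_KG, n), 42.0, 95.0)
    return [AnatomyParams(sex_code=float(s), height_cm=float(h), mass_kg=float(m))
            for s, h, m in zip(sexes, heights, masses)]


def _sample_errors(n: int, rng: np.random.Generator,
                   sd_cm: float = 1.0, max_cm: float = 3.0) -> np.ndarray:
    """Anatomical-error draws: Normal(0, sd) truncated to ±max, per component."""
    out = np.empty((n, 3))
    for i in range(n):
        for j in range(3):
            while True:
                x = rng.normal(0.0, sd_cm)
                if abs(x) <= max_cm:
                    out[i, j] = x
                    break
    return out


@dataclass
class ParticipantBundle:
    """Everything generated for one synthetic participant."""

    id: int
    params: AnatomyParams
    errors_cm: np.ndarray
    truth_model: ShoulderModel | None = None
    sg_model: ShoulderModel | None = None


def generate_cohort(n: int = 12, coefficient_vector=None, noise_sd: float = 2.0,
                    seed: int = 0, mode: str = "linear",
                    tasks=("AA", "FE", "IER"), error_sd_cm: float = 1.0,
                    error_max_cm: float = 3.0, ik_stride: int = 10,
                    build_models: bool = False, allow_small: bool = False):
    """Synthetic cohort: ``(bundles, cohort_table)``.

    ``linear`` mode draws ΔROM directly from the regression model
    (coefficients + Normal(0, noise_sd) residuals) — fast, for
    parameter-recovery work. ``mechanistic`` mode computes ΔROM by actually
    running noiseless trials of each task through IK with both the truth
    and the error-injected scaled-generic model (see
    :func:`shoulderkin.pipeline.mechanistic_delta_rom`).
    """
    if n < 7 and not allow_small:
        # the five-predictor regression needs n > 6; small cohorts are only
        # meaningful for kinematics-only work (allow_small)
        raise ValidationError("cohort must have at least 7 participants")
    if mode not in ("linear", "mechanistic"):
        raise ValidationError(f"unknown cohort mode {mode!r}")
    rng = np.random.default_rng(seed)
    beta = np.asarray(
        DEFAULT_COEFFICIENTS if coefficient_vector is None else coefficient_vector,
        dtype=float,
    )
    if beta.shape != (6,):
        raise ValidationError("coefficient_vector must have 6 entries (intercept + 5)")
    participants = _sample_anthropometrics(n, rng)
    errors = _sample_errors(n, rng, sd_cm=error_sd_cm, max_cm=error_max_cm)
    bundles = []
    rows = []
    for i, (params, err) in enumerate(zip(participants, errors)):
        bundle = ParticipantBundle(id=i, params=params, errors_cm=err)
        if mode == "mechanistic" or build_models:
            _, _, truth = generate_anatomy(params, seed=seed * 100003 + i)
            bundle.truth_model = truth
            bundle.sg_model = make_scaled_generic(truth, err)
        bundles.append(bundle)
        x = np.array([1.0, params.sex_code, params.bmi, *err])
        for task in tasks:
            if mode == "linear":
                drom = float(x @ beta + rng.normal(0.0, noise_sd))
            else:
                from .pipeline import mechanistic_delta_rom

                drom = mechanistic_delta_rom(
                    bundle.truth_model, bundle.sg_model, task, ik_stride=ik_stride
                )
            rows.append({
                "id": i, "task": task, "delta_rom": drom,
                "sex_code": params.sex_code, "bmi": params.bmi,
                "delta_clavicle": err[0], "delta_scapula": err[1],
                "delta_humerus": err[2],
            })
    import pandas as pd

    return bundles, pd.DataFrame(rows, columns=list(COHORT_TABLE_COLUMNS))


COHORT_TABLE_COLUMNS = ("id", "task", "delta_rom", "sex_code", "bmi",
                        "delta_clavicle", "delta_scapula", "delta_humerus")
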