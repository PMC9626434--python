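"""Marker-based (direct) kinematics.

Segment poses are obtained by least-squares rigid registration of tracked
markers, wand-registered scapular landmarks are reconstructed from the
cluster pose, the functional GHJ centre is localized with the symmetrical
centre-of-rotation estimation (SCoRE) linear system, and glenohumeral
angles are extracted per frame as the YXZ Cardan decomposition of the
humerus orientation relative to the scapula — the DirectK reference that
the model-based inverse kinematics is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import CoordinateSystem, LandmarkSet, humerus_cs, scapula_cs
from .exceptions import DegenerateGeometryError, ValidationError
from .rotations import cardan_yxz_from_rotation

__all__ = [
    "MarkerTrajectorySet",
    "ClusterCalibration",
    "rigid_register",
    "reconstruct_landmarks",
    "score_joint_centre",
    "direct_ghj_angles",
    "DirectKResult",
]


@dataclass
class MarkerTrajectorySet:
    """Labelled marker positions over frames.

    ``positions`` is (frames, markers, 3) metres; missing observations are
    NaN. ``events`` holds named frame indices such as phase boundaries.
    """

    labels: list
    positions: np.ndarray
    rate: float
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must be a (frames, markers, 3) array")
        if self.positions.shape[1] != len(self.labels):
            raise ValidationError("label count does not match position array width")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def frame(self, i: int) -> dict:
        """Markers observed at frame ``i`` (NaN entries dropped)."""
        out = {}
        for j, name in enumerate(self.labels):
            p = self.positions[i, j]
            if np.all(np.isfinite(p)):
                out[name] = p
        return out

    def index(self, name: str) -> int:
        return self.labels.index(name)


def rigid_register(local_points: dict, observed: dict) -> tuple[CoordinateSystem, float]:
    """Optimal rigid transform mapping local to observed points (Kabsch).

    Solves ``min Σ ‖R·l + t − o‖²`` over proper rotations via SVD with the
    reflection-correcting sign convention, using the markers named in both
    sets. Returns the pose as a :class:`CoordinateSystem` (axes = R,
    origin = t) and the RMS residual in metres.
    """
    common = [n for n in local_points if n in observed]
    if len(common) < 3:
        raise DegenerateGeometryError(
            f"rigid registration needs >= 3 common points, got {len(common)}"
        )
    L = np.array([np.asarray(local_points[n], float) for n in common])
    O = np.array([np.asarray(observed[n], float) for n in common])
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(O))):
        raise ValidationError("registration points contain non-finite values")
    Lc = L - L.mean(axis=0)
    sv = np.linalg.svd(Lc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):
        raise DegenerateGeometryError("registration points are collinear")
    Oc = O - O.mean(axis=0)
    H = Lc.T @ Oc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = O.mean(axis=0) - R @ L.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((L @ R.T + t - O) ** 2, axis=1))))
    return CoordinateSystem(origin=t, axes=R), rms


def reconstruct_landmarks(cluster_pose: CoordinateSystem, stored_local) -> LandmarkSet:
    """World positions of landmarks stored in the cluster/segment frame."""
    stored = stored_local if isinstance(stored_local, LandmarkSet) else LandmarkSet(stored_local)
    return LandmarkSet({n: cluster_pose.transform(p) for n, p in stored.items()})


def score_joint_centre(poses_parent, poses_child) -> tuple[np.ndarray, np.ndarray, float]:
    """SCoRE functional joint centre from paired segment pose trajectories.

    Finds the point that is stationary in both segment frames: with parent
    poses (R1, t1) and child poses (R2, t2), solves the stacked linear
    system ``R1·c1 − R2·c2 = t2 − t1`` for the centre expressed in each
    local frame. Returns ``(c_parent, c_child, rms)`` where rms is the RMS
    distance between the two world-frame centre reconstructions.
    """
    if len(poses_parent) != len(poses_child):
        raise ValidationError("pose trajectories must have equal length")
    n = len(poses_parent)
    if n < 3:
        raise ValidationError("SCoRE needs at least 3 pose pairs")
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, (pa, pc) in enumerate(zip(poses_parent, poses_child)):
        A[3 * i: 3 * i + 3, :3] = pa.axes
        A[3 * i: 3 * i + 3, 3:] = -pc.axes
        b[3 * i: 3 * i + 3] = pc.origin - pa.origin
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6:
        raise DegenerateGeometryError(
            "SCoRE system is rank deficient (insufficient relative rotation)"
        )
    c_parent, c_child = sol[:3], sol[3:]
    resid = A @ sol - b
    rms = float(np.sqrt(np.mean(np.sum(resid.reshape(-1, 3) ** 2, axis=1))))
    return c_parent, c_child, rms


@dataclass
class ClusterCalibration:
    """Static-trial calibration of the scapular cluster.

    All entries are expressed in the scapula segment frame captured during
    calibration: the cluster marker positions, the wand-registered scapular
    landmarks (AA, TS, AI, optionally PC) and the GHJ centre (functional
    SCoRE estimate or model-based sphere fit).
    """

    cluster_local: dict
    scapular_landmarks_local: LandmarkSet
    gh_local: np.ndarray

    def __post_init__(self):
        self.cluster_local = {k: np.asarray(v, float) for k, v in self.cluster_local.items()}
        if len(self.cluster_local) < 3:
            raise ValidationError("cluster calibration needs >= 3 cluster markers")
        self.scapular_landmarks_local = LandmarkSet(self.scapular_landmarks_local)
        self.scapular_landmarks_local.require("AA", "TS", "AI", context="cluster calibration")
        self.gh_local = np.asarray(self.gh_local, dtype=float)

    @classmethod
    def from_model(cls, model) -> "ClusterCalibration":
        """Ideal calibration extracted from a model's scapula segment."""
        scap = model.segments["scapula"]
        return cls(
            cluster_local=dict(scap.local_markers),
            scapular_landmarks_local=LandmarkSet(
                {n: p for n, p in scap.local_landmarks.items() if n in ("AA", "TS", "AI", "PC")}
            ),
            gh_local=model.joint("GHJ").centre_in_parent,
        )


@dataclass
class DirectKResult:
    """Per-frame GHJ Cardan angles computed directly from markers."""

    times: np.ndarray
    angles: np.ndarray        # (frames, 3): ghj_y, ghj_x, ghj_z in degrees
    gimbal_flags: np.ndarray  # bool per frame
    valid: np.ndarray         # bool per frame; False where markers were missing
    rate: float

    def angle_dict(self) -> dict:
        return {
            "ghj_y": self.angles[:, 0],
            "ghj_x": self.angles[:, 1],
            "ghj_z": self.angles[:, 2],
        }


def direct_ghj_angles(markers: MarkerTrajectorySet,
                      calibration: ClusterCalibration) -> DirectKResult:
    """DirectK: GHJ YXZ Cardan angles straight from experimental markers.

    Per frame: the scapula pose is registered from the cluster markers,
    the wand-calibrated scapular landmarks and GHJ centre are reconstructed
    from that pose, ISB scapula and humerus frames are built, and the GHJ
    rotation (scapulaᵀ·humerus) is decomposed with the YXZ Cardan sequence.
    Frames with missing required markers are flagged and set to NaN.
    """
    n = markers.n_frames
    if n == 0:
        raise ValidationError("empty marker trajectory")
    angles = np.full((n, 3), np.nan)
    gimbal = np.zeros(n, dtype=bool)
    valid = np.zeros(n, dtype=bool)
    cluster_names = set(calibration.cluster_local)
    for i in range(n):
        obs = markers.frame(i)
        if len(cluster_names & set(obs)) < 3 or "EL" not in obs or "EM" not in obs:
            continue
        try:
            pose, _ = rigid_register(calibration.cluster_local, obs)
        except DegenerateGeometryError:
            continue
        recon = reconstruct_landmarks(pose, calibration.scapular_landmarks_local)
        scap = scapula_cs(recon)
        gh_world = pose.transform(calibration.gh_local)
        hum = humerus_cs(LandmarkSet({"EL": obs["EL"], "EM": obs["EM"]}), gh_world)
        c = cardan_yxz_from_rotation(scap.axes.T @ hum.axes)
        angles[i] = (c.alpha_y, c.beta_x, c.gamma_z)
        gimbal[i] = c.gimbal
        valid[i] = True
    return DirectKResult(times=markers.times, angles=angles,
                         gimbal_flags=gimbal, valid=valid, rate=markers.rate)


def thorax_pose_trajectory(markers: MarkerTrajectorySet, thorax_local: dict):
    """Per-frame thorax pose by rigid registration of the thorax markers."""
    poses = []
    for i in range(markers.n_frames):
        obs = markers.frame(i)
        try:
            pose, _ = rigid_register(thorax_local, obs)
        except DegenerateGeometryError:
            pose = None
        poses.append(pose)
    return poses
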