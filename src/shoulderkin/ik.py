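"""Forward and inverse kinematics of the 8-DOF shoulder chain.

Inverse kinematics follows the global-optimization formulation: at every
frame the generalized coordinates minimize the weighted squared distance
between experimental markers and the model's virtual markers, which keeps
the joints congruent by construction (rotations only, coincident joint
centres). The thorax pose is first fixed by rigid registration of the
thorax markers (optionally co-optimized), then the 8 joint coordinates are
found with Levenberg–Marquardt, warm-started frame to frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .anatomy import DOF_NAMES, CoordinateSystem, ShoulderModel
from .directk import MarkerTrajectorySet, rigid_register
from .exceptions import DegenerateGeometryError, ValidationError
from .rotations import cardan_yxz_from_rotation

__all__ = [
    "forward_kinematics",
    "ik_solve_frame",
    "ik_solve_trajectory",
    "marker_rmsd",
    "thoracohumeral_elevation",
    "FrameSolution",
    "IKResult",
    "RMSD_TOLERANCE_M",
]

#: global marker-RMSd acceptance threshold (m); exceeding it warns, not fails
RMSD_TOLERANCE_M = 0.025

_SEG_INDEX = {"thorax": 0, "clavicle": 1, "scapula": 2, "humerus": 3}


def _r_yxz(a: float, b: float, c: float) -> np.ndarray:
    """Ry(a)·Rx(b)·Rz(c), radians (closed form for the hot path)."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array([
        [ca * cc + sa * sb * sc, -ca * sc + sa * sb * cc, sa * cb],
        [cb * sc, cb * cc, -sb],
        [-sa * cc + ca * sb * sc, sa * sc + ca * sb * cc, ca * cb],
    ])


class _FKEngine:
    """Precompiled chain for fast repeated forward-kinematics evaluation."""

    def __init__(self, model: ShoulderModel, marker_names=None):
        self.model = model
        self.joints = [
            (j.centre_in_parent, j.centre_in_child, j.rest_rotation)
            for j in model.joints
        ]
        owner = model.marker_segments()
        if marker_names is None:
            marker_names = list(owner)
        self.marker_names = list(marker_names)
        self.marker_owner = np.array(
            [_SEG_INDEX[owner[m]] for m in self.marker_names], dtype=int
        )
        self.locals = (
            np.array([model.segments[owner[m]].local_markers[m] for m in self.marker_names])
            if self.marker_names else np.zeros((0, 3))
        )

    def poses(self, q_rad: np.ndarray, thorax_R: np.ndarray, thorax_o: np.ndarray):
        """Segment poses [(R, o) x 4] for generalized coordinates in radians."""
        Rj = [
            _r_yxz(q_rad[0], q_rad[1], 0.0),       # SCJ: 2-DOF universal, Y then X
            _r_yxz(q_rad[2], q_rad[3], q_rad[4]),  # ACJ
            _r_yxz(q_rad[5], q_rad[6], q_rad[7]),  # GHJ
        ]
        poses = [(thorax_R, thorax_o)]
        for (cp, cc, rest), R_joint in zip(self.joints, Rj):
            Rp, op = poses[-1]
            centre_world = op + Rp @ cp
            Rc = Rp @ R_joint @ rest
            oc = centre_world - Rc @ cc
            poses.append((Rc, oc))
        return poses

    def markers(self, q_rad, thorax_R, thorax_o) -> np.ndarray:
        poses = self.poses(q_rad, thorax_R, thorax_o)
        out = np.empty((len(self.marker_names), 3))
        for k in range(4):
            sel = self.marker_owner == k
            if np.any(sel):
                R, o = poses[k]
                out[sel] = self.locals[sel] @ R.T + o
        return out


def forward_kinematics(model: ShoulderModel, q, thorax_pose: CoordinateSystem,
                       include_landmarks: bool = False) -> dict:
    """World positions of the model's markers (and optionally landmarks).

    ``q`` is the 8-vector of generalized coordinates in degrees, ordered as
    :data:`~shoulderkin.anatomy.DOF_NAMES`. Poses compose along the chain as
    ``T(centre_in_parent) · R(q) · R_rest · T(−centre_in_child)`` so the
    two sides of every joint stay coincident for any q.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (8,):
        raise ValidationError("q must be an 8-vector of joint angles in degrees")
    if not np.all(np.isfinite(q)):
        raise ValidationError("q contains non-finite values")
    engine = _FKEngine(model)
    poses = engine.poses(np.deg2rad(q), thorax_pose.axes, thorax_pose.origin)
    out = {}
    for seg_name, k in _SEG_INDEX.items():
        R, o = poses[k]
        seg = model.segments[seg_name]
        for m, p in seg.local_markers.items():
            out[m] = R @ p + o
        if include_landmarks:
            for n, p in seg.local_landmarks.items():
                out.setdefault(f"{seg_name}:{n}", R @ p + o)
    return out


def segment_poses(model: ShoulderModel, q, thorax_pose: CoordinateSystem) -> dict:
    """Per-segment world poses as CoordinateSystems at coordinates ``q`` (deg)."""
    engine = _FKEngine(model, marker_names=[])
    poses = engine.poses(np.deg2rad(np.asarray(q, float)), thorax_pose.axes, thorax_pose.origin)
    return {
        name: CoordinateSystem(origin=poses[k][1], axes=poses[k][0])
        for name, k in _SEG_INDEX.items()
    }


def marker_rmsd(observed: dict, virtual: dict, weights: dict | None = None) -> float:
    """Weighted RMS deviation between matching markers: sqrt(Σw‖Δ‖²/Σw)."""
    common = [n for n in observed if n in virtual]
    if not common:
        raise ValidationError("no common markers between observed and virtual sets")
    w = np.array([1.0 if weights is None else weights.get(n, 1.0) for n in common])
    if np.any(w < 0):
        raise ValidationError("marker weights must be non-negative")
    if w.sum() <= 0:
        raise ValidationError("all marker weights are zero")
    d2 = np.array([
        np.sum((np.asarray(observed[n], float) - np.asarray(virtual[n], float)) ** 2)
        for n in common
    ])
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


@dataclass
class FrameSolution:
    """Single-frame IK solution."""

    q: np.ndarray                  # 8 joint angles, degrees
    rms: float                     # weighted marker RMS residual, metres
    thorax_pose: CoordinateSystem
    converged: bool
    n_evaluations: int = 0


def _prepare_weights(names, weights):
    w = np.array([1.0 if weights is None else float(weights.get(n, 1.0)) for n in names])
    if np.any(w < 0):
        raise ValidationError("marker weights must be non-negative")
    return w


def ik_solve_frame(model: ShoulderModel, observed: dict, weights: dict | None = None,
                   q_init=None, thorax_pose: CoordinateSystem | None = None,
                   optimize_thorax: bool = False, max_nfev: int = 900,
                   _engine: _FKEngine | None = None) -> FrameSolution:
    """Solve one frame: q minimizing Σ wᵢ‖mᵢ_obs − mᵢ_model(q)‖².

    The thorax pose is registered from the thorax markers first (or taken
    from ``thorax_pose``); set ``optimize_thorax=True`` to co-optimize a
    6-DOF thorax correction with the 8 joint coordinates. Non-convergence
    returns the best-found q with ``converged=False``.
    """
    owner = model.marker_segments()
    engine = _engine or _FKEngine(model)
    present = [m for m in engine.marker_names if m in observed
               and np.all(np.isfinite(observed[m]))]
    thorax_names = [m for m in present if owner[m] == "thorax"]
    distal_names = [m for m in present if owner[m] != "thorax"]
    w_all = _prepare_weights(present, weights)
    if w_all.sum() <= 0:
        raise ValidationError("all marker weights are zero: IK is unconstrained")

    if thorax_pose is None:
        thorax_local = {m: model.segments["thorax"].local_markers[m] for m in thorax_names}
        obs_thorax = {m: observed[m] for m in thorax_names}
        thorax_pose, _ = rigid_register(thorax_local, obs_thorax)
    if not distal_names:
        raise DegenerateGeometryError("no distal markers observed: joint DOF unconstrained")

    sub = _FKEngine(model, marker_names=distal_names) if not optimize_thorax else \
        _FKEngine(model, marker_names=present)
    target = np.array([observed[m] for m in sub.marker_names])
    sw = np.sqrt(_prepare_weights(sub.marker_names, weights))[:, None]

    q0 = np.zeros(8) if q_init is None else np.asarray(q_init, dtype=float)
    x0 = np.deg2rad(q0)
    # MINPACK differentiates with steps relative to |x|; snap (de)normal-tiny
    # entries to exactly zero so it falls back to its absolute step there
    x0[np.abs(x0) < 1e-9] = 0.0
    R0, o0 = thorax_pose.axes, thorax_pose.origin

    if optimize_thorax:
        x0 = np.r_[x0, np.zeros(6)]

        def resid(x):
            Rt = R0 @ _r_yxz(x[8], x[9], x[10])
            ot = o0 + x[11:14]
            return ((sub.markers(x[:8], Rt, ot) - target) * sw).ravel()
    else:
        def resid(x):
            return ((sub.markers(x, R0, o0) - target) * sw).ravel()

    fit = least_squares(resid, x0, method="lm", xtol=1e-10, ftol=1e-12,
                        max_nfev=max_nfev)
    q = np.rad2deg(fit.x[:8])
    q = (q + 180.0) % 360.0 - 180.0  # wrap equivalent angles into (-180, 180]
    if optimize_thorax:
        thorax_pose = CoordinateSystem(
            origin=o0 + fit.x[11:14], axes=R0 @ _r_yxz(fit.x[8], fit.x[9], fit.x[10])
        )
    # report the RMS over every observed model marker, thorax included
    virtual_all = _FKEngine(model, marker_names=present)
    v = virtual_all.markers(np.deg2rad(q), thorax_pose.axes, thorax_pose.origin)
    d2 = np.sum((v - np.array([observed[m] for m in present])) ** 2, axis=1)
    rms = float(np.sqrt(np.sum(w_all * d2) / np.sum(w_all)))
    return FrameSolution(q=q, rms=rms, thorax_pose=thorax_pose,
                         converged=bool(fit.status > 0),
                         n_evaluations=int(fit.nfev))


@dataclass
class IKResult:
    """Trajectory IK solution.

    ``global_rmsd`` pools squared weighted marker residuals over all valid
    frames and markers; flagged (invalid/unconverged) frames are excluded.
    """

    frame_indices: np.ndarray
    times: np.ndarray
    q_trajectory: np.ndarray     # (frames, 8) degrees; NaN where invalid
    per_frame_rms: np.ndarray    # metres
    global_rmsd: float           # metres
    valid: np.ndarray            # bool per solved frame
    converged: np.ndarray        # bool per solved frame
    thorax_poses: list
    dof_names: tuple = DOF_NAMES

    def ghj_cardan(self, model: ShoulderModel) -> np.ndarray:
        """Realized GHJ YXZ Cardan angles (deg), scapula-relative: (F, 3) as
        (ghj_y, ghj_x, ghj_z). Equals the GHJ rows of q when the model's
        rest orientation at the GHJ is the identity."""
        rest = model.joint("GHJ").rest_rotation
        out = np.full((len(self.q_trajectory), 3), np.nan)
        for i, q in enumerate(self.q_trajectory):
            if not np.all(np.isfinite(q)):
                continue
            qr = np.deg2rad(q)
            R = _r_yxz(qr[5], qr[6], qr[7]) @ rest
            c = cardan_yxz_from_rotation(R)
            out[i] = (c.alpha_y, c.beta_x, c.gamma_z)
        return out

    def angle_dict(self) -> dict:
        return {name: self.q_trajectory[:, k] for k, name in enumerate(DOF_NAMES)}


def ik_solve_trajectory(model: ShoulderModel, markers: MarkerTrajectorySet,
                        weights: dict | None = None, stride: int = 1,
                        optimize_thorax: bool = False) -> IKResult:
    """Frame-sequential IK with warm starts.

    Frame 0 starts from the anatomical neutral q = 0; subsequent frames
    start from the previous solution. ``stride`` solves every n-th frame
    (the full-rate trajectory can be recovered by interpolation when
    needed). Frames whose markers cannot constrain the chain are flagged
    and excluded from the pooled RMSd.
    """
    if markers.n_frames == 0:
        raise ValidationError("empty marker trajectory")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    engine = _FKEngine(model)
    idx = np.arange(0, markers.n_frames, stride)
    nq = len(idx)
    q_traj = np.full((nq, 8), np.nan)
    rms = np.full(nq, np.nan)
    valid = np.zeros(nq, dtype=bool)
    conv = np.zeros(nq, dtype=bool)
    poses = []
    sum_sq, sum_w = 0.0, 0.0
    owner = model.marker_segments()
    q_prev = None
    for k, i in enumerate(idx):
        obs = markers.frame(int(i))
        try:
            sol = ik_solve_frame(model, obs, weights=weights, q_init=q_prev,
                                 optimize_thorax=optimize_thorax, _engine=engine)
        except (DegenerateGeometryError, ValidationError):
            poses.append(None)
            continue
        q_traj[k] = sol.q
        rms[k] = sol.rms
        valid[k] = True
        conv[k] = sol.converged
        poses.append(sol.thorax_pose)
        q_prev = sol.q
        present = [m for m in engine.marker_names if m in obs]
        w = _prepare_weights(present, weights)
        sum_sq += (sol.rms ** 2) * w.sum()
        sum_w += w.sum()
    if sum_w == 0:
        raise ValidationError("no frame could be solved")
    return IKResult(
        frame_indices=idx,
        times=idx / markers.rate,
        q_trajectory=q_traj,
        per_frame_rms=rms,
        global_rmsd=float(np.sqrt(sum_sq / sum_w)),
        valid=valid,
        converged=conv,
        thorax_poses=poses,
    )


def thoracohumeral_elevation(model: ShoulderModel, q_trajectory) -> np.ndarray:
    """Angle (deg) between the thorax and humerus long (Y) axes per frame.

    0° with the arm hanging along the thorax, 90° at shoulder level.
    """
    q_arr = np.atleast_2d(np.asarray(q_trajectory, dtype=float))
    rests = [j.rest_rotation for j in model.joints]
    out = np.full(len(q_arr), np.nan)
    for i, q in enumerate(q_arr):
        if not np.all(np.isfinite(q)):
            continue
        qr = np.deg2rad(q)
        R = (_r_yxz(qr[0], qr[1], 0.0) @ rests[0]
             @ _r_yxz(qr[2], qr[3], qr[4]) @ rests[1]
             @ _r_yxz(qr[5], qr[6], qr[7]) @ rests[2])
        out[i] = np.rad2deg(np.arccos(np.clip(R[1, 1], -1.0, 1.0)))
    return out
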