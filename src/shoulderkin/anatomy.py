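"""ISB segment coordinate systems and the 4-segment, 8-DOF shoulder model.

The kinematic chain is thorax → clavicle → scapula → humerus, articulated
by the sternoclavicular joint (SCJ, 2-DOF universal), the acromioclavicular
joint (ACJ, 3-DOF ball) and the glenohumeral joint (GHJ, 3-DOF ball):
eight generalized coordinates in total. Two construction paths are
provided: assembly from a participant's own landmarks (the image-based
route) and linear scaling of a generic template to a participant's
measurements (the scaled-generic route). Anatomical errors between two
models are the signed differences of the three inter-joint distances.

Conventions: metres, right-handed frames, world Y up, X anterior, Z to the
participant's right. All models are of a right shoulder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateGeometryError,
    MissingLandmarkError,
    ValidationError,
)

__all__ = [
    "LandmarkSet",
    "CoordinateSystem",
    "Segment",
    "JointDefinition",
    "ShoulderModel",
    "ScaleSpec",
    "AnatomicalErrors",
    "thorax_cs",
    "clavicle_cs",
    "scapula_cs",
    "humerus_cs",
    "fit_sphere",
    "assemble_model",
    "scale_generic",
    "anatomical_errors",
    "SEGMENT_NAMES",
    "DOF_NAMES",
]

SEGMENT_NAMES = ("thorax", "clavicle", "scapula", "humerus")

#: generalized-coordinate layout of the 8-DOF chain, degrees
DOF_NAMES = (
    "scj_y", "scj_x",
    "acj_y", "acj_x", "acj_z",
    "ghj_y", "ghj_x", "ghj_z",
)

_KNOWN_LANDMARKS = frozenset(
    {"C7", "T8", "IJ", "PX", "SC", "AC", "AA", "TS", "AI", "PC", "EL", "EM", "GH"}
)


def _as_vec3(v, what="vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"{what} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{what} contains non-finite values")
    return v


class LandmarkSet(dict):
    """Named bony-landmark positions (metres). A thin dict of 3-vectors."""

    def __init__(self, positions=()):
        super().__init__()
        for name, pos in dict(positions).items():
            self[name] = pos

    def __setitem__(self, name, pos):
        super().__setitem__(str(name), _as_vec3(pos, f"landmark {name!r}"))

    def require(self, *names, context=""):
        missing = [n for n in names if n not in self]
        if missing:
            raise MissingLandmarkError(missing, context)
        return tuple(self[n] for n in names)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)):
        R = np.asarray(rotation, dtype=float)
        t = _as_vec3(translation, "translation")
        return LandmarkSet({n: R @ p + t for n, p in self.items()})


@dataclass(frozen=True)
class CoordinateSystem:
    """Right-handed frame: origin plus a rotation whose columns are X, Y, Z."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise ValidationError("axes must be a 3x3 matrix")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise ValidationError("axes are not orthonormal to 1e-9")
        if np.linalg.det(axes) < 0:
            raise ValidationError("axes are left-handed (det < 0)")
        object.__setattr__(self, "axes", axes)

    def transform(self, points):
        """Map local coordinates to the parent/world frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.axes.T + self.origin

    def inverse_transform(self, points):
        """Map parent/world coordinates into this frame."""
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.axes


def _orthonormal_cs(origin, primary, primary_axis, secondary, secondary_axis, context):
    """Build a frame from a primary direction and a secondary hint.

    ``primary`` becomes exactly the ``primary_axis``; the ``secondary`` hint
    is orthogonalized against it. Axis labels are 0=X, 1=Y, 2=Z, and the
    third axis completes the right-handed triad.
    """
    p = np.asarray(primary, float)
    np_ = np.linalg.norm(p)
    s = np.asarray(secondary, float)
    if np_ < 1e-12 or np.linalg.norm(s) < 1e-12:
        raise DegenerateGeometryError(f"{context}: zero-length axis direction")
    p = p / np_
    s = s - (s @ p) * p
    ns = np.linalg.norm(s)
    if ns < 1e-9:
        raise DegenerateGeometryError(f"{context}: collinear landmark geometry")
    s = s / ns
    axes = np.empty((3, 3))
    axes[:, primary_axis] = p
    axes[:, secondary_axis] = s
    third = 3 - primary_axis - secondary_axis
    # choose the sign that keeps det = +1 for the cyclic order X, Y, Z
    t = np.cross(p, s)
    cyclic = {(1, 2): 0, (2, 0): 1, (0, 1): 2}
    if cyclic.get((primary_axis, secondary_axis)) == third:
        axes[:, third] = t
    else:
        axes[:, third] = -t
    if np.linalg.det(axes) < 0:  # pragma: no cover - construction guarantees +1
        axes[:, third] = -axes[:, third]
    return CoordinateSystem(origin=origin, axes=axes)


def thorax_cs(landmarks: LandmarkSet) -> CoordinateSystem:
    """ISB thorax frame.

    Origin IJ; Y from the midpoint of PX and T8 toward the midpoint of IJ
    and C7 (cranial); Z perpendicular to the IJ–C7–mid(PX, T8) plane
    pointing right; X = Y × Z (anterior).
    """
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    ij, c7, px, t8 = lm.require("IJ", "C7", "PX", "T8", context="thorax frame")
    upper = 0.5 * (ij + c7)
    lower = 0.5 * (px + t8)
    y = upper - lower
    z_hint = np.cross(c7 - ij, lower - ij)  # right-pointing for a right-handed setup
    if np.linalg.norm(z_hint) < 1e-12:
        raise DegenerateGeometryError("thorax frame: IJ, C7 and mid(PX, T8) are collinear")
    return _orthonormal_cs(ij, y, 1, z_hint, 2, "thorax frame")


def clavicle_cs(landmarks: LandmarkSet) -> CoordinateSystem:
    """ISB clavicle frame: origin SC, Z along SC→AC, Y close to thorax Y."""
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    sc, ac = lm.require("SC", "AC", context="clavicle frame")
    thorax = thorax_cs(lm)  # the ISB clavicle frame borrows the thorax vertical
    z = ac - sc
    return _orthonormal_cs(sc, z, 2, thorax.axes[:, 1], 1, "clavicle frame")


def scapula_cs(landmarks: LandmarkSet) -> CoordinateSystem:
    """ISB scapula frame.

    Origin AA; Z along TS→AA; X perpendicular to the AA–AI–TS plane
    pointing forward; Y = Z × X.
    """
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    aa, ts, ai = lm.require("AA", "TS", "AI", context="scapula frame")
    z = aa - ts
    x = np.cross(aa - ts, ai - ts)  # anterior for a right scapula
    if np.linalg.norm(x) < 1e-12:
        raise DegenerateGeometryError("scapula frame: AA, TS, AI are collinear")
    return _orthonormal_cs(aa, z, 2, x, 0, "scapula frame")


def humerus_cs(landmarks: LandmarkSet, gh_centre=None) -> CoordinateSystem:
    """ISB humerus frame.

    Origin GH; Y from the elbow centre (midpoint of EL and EM) toward GH;
    X perpendicular to the GH–EL–EM plane pointing forward; Z = X × Y.
    """
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    if gh_centre is None:
        (gh,) = lm.require("GH", context="humerus frame")
    else:
        gh = _as_vec3(gh_centre, "gh_centre")
    el, em = lm.require("EL", "EM", context="humerus frame")
    mid = 0.5 * (el + em)
    y = gh - mid
    x = np.cross(em - el, y)  # anterior for a right arm (EL lateral, EM medial)
    if np.linalg.norm(x) < 1e-12:
        raise DegenerateGeometryError("humerus frame: GH, EL, EM are collinear")
    return _orthonormal_cs(gh, y, 1, x, 0, "humerus frame")


_CS_BUILDERS = {
    "thorax": thorax_cs,
    "clavicle": clavicle_cs,
    "scapula": scapula_cs,
    "humerus": humerus_cs,
}


def fit_sphere(points) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere fit: algebraic seed then Gauss–Newton refinement.

    Returns ``(centre, radius, rms_residual)`` where the residual of point
    ``p`` is ``|‖p − c‖ − r|``. Requires at least 5 non-coplanar points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("points must be an (n, 3) array")
    if len(pts) < 5:
        raise DegenerateGeometryError("sphere fit needs at least 5 points")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1e-12):
        raise DegenerateGeometryError("sphere fit: points are (nearly) coplanar")
    # algebraic (Coope) fit: ‖p‖² = 2 c·p + (r² − ‖c‖²), linear in (c, k)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0, k = sol[:3], sol[3]
    r0 = np.sqrt(max(k + c0 @ c0, 0.0))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    fit = least_squares(resid, np.r_[c0, r0], method="lm", xtol=1e-14, ftol=1e-14)
    centre, radius = fit.x[:3], float(fit.x[3])
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return centre, radius, rms


@dataclass
class Segment:
    """Rigid segment: landmarks and marker attachment points in its ISB frame."""

    name: str
    local_landmarks: LandmarkSet
    local_markers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValidationError(f"unknown segment name {self.name!r}")
        self.local_landmarks = LandmarkSet(self.local_landmarks)
        self.local_markers = {k: _as_vec3(v, f"marker {k!r}") for k, v in self.local_markers.items()}


@dataclass
class JointDefinition:
    """Rotational joint between two segments.

    The joint centre is stored in both the parent and child frames and is
    coincident by construction (no translational freedom). ``rest_rotation``
    is the child-frame orientation relative to the parent frame at the
    assembly posture, so q = 0 reproduces the posture the model was built
    in; the generalized rotations act about the parent-frame joint axes.
    """

    name: str
    parent: str
    child: str
    centre_in_parent: np.ndarray
    centre_in_child: np.ndarray
    dof_count: int
    rotation_sequence: tuple
    rest_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if self.name not in ("SCJ", "ACJ", "GHJ"):
            raise ValidationError(f"unknown joint name {self.name!r}")
        expected = 2 if self.name == "SCJ" else 3
        if self.dof_count != expected:
            raise ValidationError(f"{self.name} must have {expected} DOF")
        if len(self.rotation_sequence) != self.dof_count:
            raise ValidationError("rotation sequence length must equal dof_count")
        self.centre_in_parent = _as_vec3(self.centre_in_parent, "centre_in_parent")
        self.centre_in_child = _as_vec3(self.centre_in_child, "centre_in_child")
        self.rest_rotation = np.asarray(self.rest_rotation, dtype=float)


@dataclass
class ShoulderModel:
    """The assembled 4-segment, 8-DOF chain rooted at the thorax."""

    segments: dict
    joints: list
    provenance: str = "mri_based"

    def __post_init__(self):
        if set(self.segments) != set(SEGMENT_NAMES):
            raise ValidationError("model must contain exactly the four chain segments")
        names = [j.name for j in self.joints]
        if names != ["SCJ", "ACJ", "GHJ"]:
            raise ValidationError("joints must be [SCJ, ACJ, GHJ] in chain order")
        if self.provenance not in ("mri_based", "scaled_generic", "synthetic_truth"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        seen = set()
        for seg in self.segments.values():
            dup = seen & set(seg.local_markers)
            if dup:
                raise ValidationError(f"duplicate marker names across segments: {sorted(dup)}")
            seen |= set(seg.local_markers)

    @property
    def dof_count(self) -> int:
        return sum(j.dof_count for j in self.joints)

    @property
    def dof_names(self) -> tuple:
        return DOF_NAMES

    def joint(self, name: str) -> JointDefinition:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def marker_segments(self) -> dict:
        """Map marker name → owning segment name."""
        return {m: s.name for s in self.segments.values() for m in s.local_markers}

    def inter_joint_distances(self) -> dict:
        """SCJ→ACJ, ACJ→GHJ and GHJ→elbow-centre distances (metres)."""
        scj, acj, ghj = self.joints
        clav = np.linalg.norm(acj.centre_in_parent - scj.centre_in_child)
        scap = np.linalg.norm(ghj.centre_in_parent - acj.centre_in_child)
        el, em = self.segments["humerus"].local_landmarks.require(
            "EL", "EM", context="humerus inter-joint distance"
        )
        hum = np.linalg.norm(0.5 * (el + em) - ghj.centre_in_child)
        return {"clavicle": float(clav), "scapula": float(scap), "humerus": float(hum)}

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "shoulderkin-model",
            "units": "m",
            "frames": "segment-local ISB frames; rotations about parent joint axes",
            "provenance": self.provenance,
            "segments": {
                s.name: {
                    "landmarks": {k: v.tolist() for k, v in s.local_landmarks.items()},
                    "markers": {k: v.tolist() for k, v in s.local_markers.items()},
                }
                for s in self.segments.values()
            },
            "joints": [
                {
                    "name": j.name,
                    "parent": j.parent,
                    "child": j.child,
                    "centre_in_parent": j.centre_in_parent.tolist(),
                    "centre_in_child": j.centre_in_child.tolist(),
                    "dof_count": j.dof_count,
                    "rotation_sequence": list(j.rotation_sequence),
                    "rest_rotation": j.rest_rotation.tolist(),
                }
                for j in self.joints
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShoulderModel":
        segments = {
            name: Segment(name, LandmarkSet(v["landmarks"]), v["markers"])
            for name, v in d["segments"].items()
        }
        joints = [
            JointDefinition(
                j["name"], j["parent"], j["child"],
                j["centre_in_parent"], j["centre_in_child"],
                j["dof_count"], tuple(j["rotation_sequence"]),
                np.asarray(j["rest_rotation"]),
            )
            for j in d["joints"]
        ]
        return cls(segments=segments, joints=joints, provenance=d["provenance"])


@dataclass(frozen=True)
class ScaleSpec:
    """Scale factors applied by the scaled-generic construction."""

    clavicle_ratio: float
    humerus_ratio: float
    scapula_ac_ts_ratio: float  # applied along the scapular Z direction
    scapula_ai_ts_ratio: float  # applied uniformly in the scapular X-Y plane
    thorax_ratios: np.ndarray   # (X, Y, Z) directional ratios

    def __post_init__(self):
        object.__setattr__(self, "thorax_ratios", _as_vec3(self.thorax_ratios, "thorax_ratios"))
        ratios = [self.clavicle_ratio, self.humerus_ratio,
                  self.scapula_ac_ts_ratio, self.scapula_ai_ts_ratio,
                  *self.thorax_ratios]
        if not all(r > 0 for r in ratios):
            raise ValidationError("all scale ratios must be positive")


@dataclass(frozen=True)
class AnatomicalErrors:
    """Signed inter-joint-distance differences (model A minus model B), cm."""

    delta_clavicle: float
    delta_scapula: float
    delta_humerus: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_clavicle, self.delta_scapula, self.delta_humerus])

    def __neg__(self):
        return AnatomicalErrors(-self.delta_clavicle, -self.delta_scapula, -self.delta_humerus)


# ---------------------------------------------------------------------------
# model assembly


def default_marker_placement(landmarks: LandmarkSet, gh_centre) -> dict:
    """Standard experimental marker set, name → (segment, world position).

    Anatomical markers sit on their landmarks (thorax C7/T8/IJ/PX, shoulder
    AC, elbow EL/EM); a three-marker cluster is placed along the scapular
    spine (AA→TS) with small out-of-line offsets so its pose is observable.
    """
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    lm.require("C7", "T8", "IJ", "PX", "AC", "EL", "EM", "AA", "TS",
               context="default marker placement")
    scap = scapula_cs(lm)
    aa, ts = lm["AA"], lm["TS"]
    spine = ts - aa
    length = np.linalg.norm(spine)
    xs, ys = scap.axes[:, 0], scap.axes[:, 1]
    # offsets proportional to the spine length, so the cluster geometry
    # scales rigidly with the scapula
    markers = {
        "C7": ("thorax", lm["C7"]),
        "T8": ("thorax", lm["T8"]),
        "IJ": ("thorax", lm["IJ"]),
        "PX": ("thorax", lm["PX"]),
        "AC": ("clavicle", lm["AC"]),
        "SSP1": ("scapula", aa + 0.15 * spine + 0.14 * length * ys),
        "SSP2": ("scapula", aa + 0.55 * spine + 0.14 * length * ys),
        "SSP3": ("scapula", aa + 0.35 * spine + 0.18 * length * ys - 0.11 * length * xs),
        "EL": ("humerus", lm["EL"]),
        "EM": ("humerus", lm["EM"]),
    }
    return markers


_LANDMARK_SEGMENTS = {
    "thorax": ("C7", "T8", "IJ", "PX", "SC"),
    "clavicle": ("SC", "AC"),
    "scapula": ("AA", "TS", "AI", "PC", "AC", "GH"),
    "humerus": ("GH", "EL", "EM"),
}


def assemble_model(landmarks: LandmarkSet, gh_centre, provenance="mri_based",
                   markers: dict | None = None) -> ShoulderModel:
    """Build the 8-DOF model from world-frame landmarks and a GHJ centre.

    Joint centres: SCJ at the SC landmark, ACJ at AC, GHJ at ``gh_centre``
    (e.g. from a humeral-head sphere fit or the functional SCoRE estimate).
    All landmark and marker positions are re-expressed in their segment's
    ISB frame; each joint stores its centre in both adjacent frames plus
    the child-vs-parent rest orientation at this posture.

    ``markers`` maps name → (segment, world position); when omitted the
    standard experimental set (:func:`default_marker_placement`) is used.
    """
    lm = landmarks if isinstance(landmarks, LandmarkSet) else LandmarkSet(landmarks)
    gh = _as_vec3(gh_centre, "gh_centre")
    world = LandmarkSet(lm)
    world["GH"] = gh
    frames = {
        "thorax": thorax_cs(world),
        "clavicle": clavicle_cs(world),
        "scapula": scapula_cs(world),
        "humerus": humerus_cs(world),
    }
    if markers is None:
        markers = default_marker_placement(world, gh)
    segments = {}
    for seg_name, frame in frames.items():
        local_lm = LandmarkSet({
            n: frame.inverse_transform(world[n])
            for n in _LANDMARK_SEGMENTS[seg_name] if n in world
        })
        local_mk = {
            m: frame.inverse_transform(_as_vec3(pos, f"marker {m!r}"))
            for m, (owner, pos) in markers.items() if owner == seg_name
        }
        segments[seg_name] = Segment(seg_name, local_lm, local_mk)

    def joint(name, parent, child, centre_world, dof, seq):
        return JointDefinition(
            name, parent, child,
            frames[parent].inverse_transform(centre_world),
            frames[child].inverse_transform(centre_world),
            dof, seq,
            frames[parent].axes.T @ frames[child].axes,
        )

    joints = [
        joint("SCJ", "thorax", "clavicle", world["SC"], 2, ("y", "x")),
        joint("ACJ", "clavicle", "scapula", world["AC"], 3, ("y", "x", "z")),
        joint("GHJ", "scapula", "humerus", gh, 3, ("y", "x", "z")),
    ]
    return ShoulderModel(segments=segments, joints=joints, provenance=provenance)


# ---------------------------------------------------------------------------
# scaled-generic construction


def _scapula_plane_ratios(ac_loc, ts_loc, ai_loc, d_ac_ts, d_ai_ts):
    """Solve the anisotropic scapula scales from the two measurements.

    Scaling by ``s_xy`` in the scapular X–Y plane and ``s_z`` along Z, both
    the AC–TS and AI–TS distances of the scaled scapula are required to
    equal the target measurements, which is a 2×2 linear system in the
    squared factors.
    """
    u = ac_loc - ts_loc
    v = ai_loc - ts_loc
    A = np.array([
        [u[0] ** 2 + u[1] ** 2, u[2] ** 2],
        [v[0] ** 2 + v[1] ** 2, v[2] ** 2],
    ])
    b = np.array([d_ac_ts ** 2, d_ai_ts ** 2])
    det = np.linalg.det(A)
    if abs(det) < 1e-16:
        raise DegenerateGeometryError(
            "scapula scaling: AC-TS and AI-TS template spans do not separate "
            "the Z and in-plane directions"
        )
    sxy2, sz2 = np.linalg.solve(A, b)
    if sxy2 <= 0 or sz2 <= 0:
        raise DegenerateGeometryError(
            "scapula scaling: target measurements are infeasible for this template"
        )
    return float(np.sqrt(sxy2)), float(np.sqrt(sz2))


def _scale_segment(seg: Segment, factors: np.ndarray) -> Segment:
    f = np.asarray(factors, dtype=float)
    return Segment(
        seg.name,
        LandmarkSet({k: v * f for k, v in seg.local_landmarks.items()}),
        {k: v * f for k, v in seg.local_markers.items()},
    )


def scale_generic(template: ShoulderModel, target: LandmarkSet, target_gh,
                  provenance: str = "scaled_generic") -> tuple[ShoulderModel, ScaleSpec]:
    """Scale a generic template to a participant's landmark measurements.

    Clavicle and humerus are scaled isotropically by their inter-joint
    distance ratios; the scapula anisotropically from the AC–TS and AI–TS
    measurements; the thorax by three directional ratios (anteroposterior
    from the IJ–C7 span, vertical from mid(IJ, C7)–mid(PX, T8), mediolateral
    from the SC–IJ width projection). Joint centres are re-derived from the
    scaled geometry.
    """
    lm = target if isinstance(target, LandmarkSet) else LandmarkSet(target)
    gh = _as_vec3(target_gh, "target_gh")
    lm.require("SC", "AC", "EL", "EM", "TS", "AI", "IJ", "C7", "PX", "T8",
               context="scale_generic target")

    segs = template.segments
    scj, acj, ghj = (template.joint(n) for n in ("SCJ", "ACJ", "GHJ"))

    # clavicle: SCJ→ACJ distance ratio
    d_clav_t = np.linalg.norm(lm["AC"] - lm["SC"])
    d_clav_g = np.linalg.norm(acj.centre_in_parent - scj.centre_in_child)
    # humerus: GHJ→elbow-centre distance ratio
    el_g, em_g = segs["humerus"].local_landmarks.require("EL", "EM")
    d_hum_g = np.linalg.norm(0.5 * (el_g + em_g) - ghj.centre_in_child)
    d_hum_t = np.linalg.norm(0.5 * (lm["EL"] + lm["EM"]) - gh)
    if min(d_clav_g, d_hum_g) < 1e-12:
        raise DegenerateGeometryError("template has a zero inter-joint distance")
    r_clav = float(d_clav_t / d_clav_g)
    r_hum = float(d_hum_t / d_hum_g)

    # scapula: two measurements
    ac_loc, ts_loc, ai_loc = segs["scapula"].local_landmarks.require("AC", "TS", "AI")
    s_xy, s_z = _scapula_plane_ratios(
        ac_loc, ts_loc, ai_loc,
        np.linalg.norm(lm["AC"] - lm["TS"]),
        np.linalg.norm(lm["AI"] - lm["TS"]),
    )

    # thorax: three directional spans measured in each model's thorax frame —
    # X (anteroposterior) from IJ-C7, Y (vertical) from the sternum/spine
    # midpoints, Z (mediolateral) from the SC-IJ width projection (SC roots
    # the clavicle on the thorax, so this is the functionally relevant width)
    def thorax_measures(pts):
        depth = abs((pts["IJ"] - pts["C7"])[0])
        height = abs((0.5 * (pts["IJ"] + pts["C7"]) - 0.5 * (pts["PX"] + pts["T8"]))[1])
        width = abs((pts["SC"] - pts["IJ"])[2])
        return np.array([depth, height, width])

    t_frame = thorax_cs(lm)
    m_target = thorax_measures(
        {k: t_frame.inverse_transform(lm[k]) for k in ("IJ", "C7", "PX", "T8", "SC")}
    )
    m_template = thorax_measures(segs["thorax"].local_landmarks)
    if np.any(m_template < 1e-12):
        raise DegenerateGeometryError("template thorax has a zero directional span")
    thorax_ratios = m_target / m_template

    spec = ScaleSpec(
        clavicle_ratio=r_clav,
        humerus_ratio=r_hum,
        scapula_ac_ts_ratio=s_z,
        scapula_ai_ts_ratio=s_xy,
        thorax_ratios=thorax_ratios,
    )

    scap_f = np.array([s_xy, s_xy, s_z])
    segments = {
        "thorax": _scale_segment(segs["thorax"], thorax_ratios),
        "clavicle": _scale_segment(segs["clavicle"], np.full(3, r_clav)),
        "scapula": _scale_segment(segs["scapula"], scap_f),
        "humerus": _scale_segment(segs["humerus"], np.full(3, r_hum)),
    }
    joints = [
        replace(scj,
                centre_in_parent=scj.centre_in_parent * thorax_ratios,
                centre_in_child=scj.centre_in_child * r_clav),
        replace(acj,
                centre_in_parent=acj.centre_in_parent * r_clav,
                centre_in_child=acj.centre_in_child * scap_f),
        replace(ghj,
                centre_in_parent=ghj.centre_in_parent * scap_f,
                centre_in_child=ghj.centre_in_child * r_hum),
    ]
    model = ShoulderModel(segments=segments, joints=joints, provenance=provenance)
    return model, spec


def anatomical_errors(model_a: ShoulderModel, model_b: ShoulderModel) -> AnatomicalErrors:
    """Signed inter-joint-distance differences, A minus B, in centimetres."""
    da = model_a.inter_joint_distances()
    db = model_b.inter_joint_distances()
    return AnatomicalErrors(
        delta_clavicle=100.0 * (da["clavicle"] - db["clavicle"]),
        delta_scapula=100.0 * (da["scapula"] - db["scapula"]),
        delta_humerus=100.0 * (da["humerus"] - db["humerus"]),
    )
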