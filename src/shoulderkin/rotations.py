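"""Elementary rotations and Euler/Cardan angle extraction.

Angles cross module boundaries in degrees; radians are used only inside
closed-form expressions. The glenohumeral joint uses the YXZ Cardan
sequence (rotation about the parent Y, then the rotated X, then Z), which
stays away from gimbal lock for arm postures near 0° or 90° of elevation
where the ISB-recommended YX'Y'' mobile-Y Euler sequence degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "CardanAnglesYXZ",
    "rot_x",
    "rot_y",
    "rot_z",
    "rotation_from_cardan_yxz",
    "cardan_yxz_from_rotation",
    "rotation_from_euler_yxy",
    "euler_yxy_from_rotation",
    "check_rotation",
]

#: critical-cosine tolerance below which a sequence is declared gimbal locked
GIMBAL_EPS = 1e-8


def rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate that ``R`` is a proper rotation matrix."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 matrix, got shape {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValidationError("rotation matrix contains non-finite entries")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValidationError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValidationError("matrix is a reflection (det < 0), not a rotation")
    return R


@dataclass(frozen=True)
class CardanAnglesYXZ:
    """YXZ Cardan decomposition, degrees: R = Ry(alpha)·Rx(beta)·Rz(gamma)."""

    alpha_y: float
    beta_x: float
    gamma_z: float
    gimbal: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_y, self.beta_x, self.gamma_z])


def rotation_from_cardan_yxz(alpha_y: float, beta_x: float, gamma_z: float) -> np.ndarray:
    return rot_y(alpha_y) @ rot_x(beta_x) @ rot_z(gamma_z)


def cardan_yxz_from_rotation(R: np.ndarray) -> CardanAnglesYXZ:
    """Extract YXZ Cardan angles (degrees) with beta in [-90, 90].

    At gimbal lock (|cos beta| < 1e-8, i.e. beta = ±90°) only the sum or
    difference of alpha and gamma is determined; gamma is set to 0, alpha
    absorbs the free angle and the result is flagged.
    """
    R = check_rotation(R)
    # R[1, 2] = -sin(beta); R[0, 2] = sin(alpha) cos(beta); R[2, 2] = cos(alpha) cos(beta)
    sb = np.clip(-R[1, 2], -1.0, 1.0)
    cb = np.hypot(R[1, 0], R[1, 1])
    beta = np.arctan2(sb, cb)
    if cb < GIMBAL_EPS:
        # R[0, 1] = sin(alpha) sin(beta), R[0, 0] = cos(alpha) (gamma folded into alpha)
        alpha = np.arctan2(sb * R[0, 1], R[0, 0])
        return CardanAnglesYXZ(np.rad2deg(alpha), np.rad2deg(beta), 0.0, gimbal=True)
    alpha = np.arctan2(R[0, 2], R[2, 2])
    gamma = np.arctan2(R[1, 0], R[1, 1])
    return CardanAnglesYXZ(np.rad2deg(alpha), np.rad2deg(beta), np.rad2deg(gamma))


def rotation_from_euler_yxy(alpha: float, beta: float, gamma: float) -> np.ndarray:
    return rot_y(alpha) @ rot_x(beta) @ rot_y(gamma)


def euler_yxy_from_rotation(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Extract YX'Y'' Euler angles (degrees), second angle in [0, 180].

    Returns ``(angles, gimbal_flag)``; the flag is raised when the second
    angle is within tolerance of 0° or 180° (sin beta ≈ 0), where the first
    and third rotations share an axis and only their sum is determined.
    """
    R = check_rotation(R)
    cb = np.clip(R[1, 1], -1.0, 1.0)
    sb = np.hypot(R[1, 0], R[1, 2])
    beta = np.arctan2(sb, cb)
    if sb < GIMBAL_EPS:
        # beta ≈ 0 or 180: R reduces to Ry(alpha ± gamma)
        alpha = np.arctan2(R[0, 2], R[0, 0])
        return np.array([np.rad2deg(alpha), np.rad2deg(beta), 0.0]), True
    alpha = np.arctan2(R[0, 1], R[2, 1])
    gamma = np.arctan2(R[1, 0], -R[1, 2])
    return np.array([np.rad2deg(alpha), np.rad2deg(beta), np.rad2deg(gamma)]), False
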