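"""Trajectory conditioning: zero-lag filtering, phase-based time
normalization, range-of-motion and trace summary statistics.

Marker trajectories are low-pass filtered before any kinematics (2nd-order
zero-lag Butterworth, 4 Hz cutoff at 200 Hz by default). Task time is
normalized so that each of the three motion phases occupies exactly one
third of the [0, 1] axis, which aligns repetitions of different cadence
before averaging or comparing traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import ValidationError

__all__ = [
    "PhaseAnnotation",
    "JointAngleTrajectory",
    "butter_lowpass_zero_lag",
    "filter_markers",
    "normalize_time",
    "rom",
    "trial_mean_sd",
    "rmsd_between",
]

TASKS = ("AA", "FE", "IER")

#: main GHJ angle analysed per task (axis of the scapula frame)
MAIN_ANGLE = {"AA": "ghj_x", "FE": "ghj_z", "IER": "ghj_y"}


@dataclass(frozen=True)
class PhaseAnnotation:
    """Three contiguous phase intervals as [start, end) frame ranges."""

    phases: tuple

    def __post_init__(self):
        phases = tuple((int(s), int(e)) for s, e in self.phases)
        if len(phases) != 3:
            raise ValidationError("exactly three phases are required")
        for (s, e) in phases:
            if e <= s:
                raise ValidationError("empty or inverted phase interval")
        for (s0, e0), (s1, _) in zip(phases, phases[1:]):
            if e0 != s1:
                raise ValidationError("phases must be contiguous and non-overlapping")
        object.__setattr__(self, "phases", phases)

    @property
    def n_frames(self) -> int:
        return self.phases[-1][1] - self.phases[0][0]

    @classmethod
    def equal_thirds(cls, n_frames: int) -> "PhaseAnnotation":
        a, b = n_frames // 3, 2 * n_frames // 3
        return cls(((0, a), (a, b), (b, n_frames)))


@dataclass
class JointAngleTrajectory:
    """Named joint-angle traces for one trial of one task.

    ``angles`` maps an angle name (e.g. ``ghj_x``) to a per-sample array in
    degrees. Before normalization ``time`` is in seconds; after
    :func:`normalize_time` the ``normalized_time`` grid spans [0, 1] with
    phase boundaries at exactly 1/3 and 2/3.
    """

    task: str
    source: str
    angles: dict
    time: np.ndarray | None = None
    normalized_time: np.ndarray | None = None
    trial: int = 0
    gimbal_flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        lengths = {len(v) for v in self.angles.values()}
        if len(lengths) > 1:
            raise ValidationError("angle traces have inconsistent lengths")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.angles.values())))

    def main_angle(self) -> np.ndarray:
        return self.angles[MAIN_ANGLE[self.task]]


def butter_lowpass_zero_lag(signal, rate: float = 200.0, cutoff: float = 4.0,
                            order: int = 2, axis: int = 0) -> np.ndarray:
    """Zero-lag low-pass Butterworth: forward-backward filtering.

    The filter is designed at ``order`` (default 2) and applied in both
    directions (``filtfilt``), cancelling phase distortion and squaring the
    magnitude response.
    """
    x = np.asarray(signal, dtype=float)
    if rate <= 2.0 * cutoff:
        raise ValidationError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff, btype="low", fs=rate)
    padlen = 3 * max(len(a), len(b))
    if x.shape[axis] <= padlen:
        raise ValidationError(
            f"signal too short for zero-lag filtering (needs > {padlen} samples)"
        )
    return filtfilt(b, a, x, axis=axis)


def filter_markers(markers, cutoff: float = 4.0, order: int = 2):
    """Low-pass filter every marker coordinate of a trajectory set.

    NaN (missing) samples are left untouched; filtering is applied to the
    finite span of each marker channel.
    """
    from .directk import MarkerTrajectorySet  # local import to avoid a cycle

    pos = markers.positions.copy()
    for j in range(pos.shape[1]):
        chan = pos[:, j, :]
        if np.all(np.isfinite(chan)):
            pos[:, j, :] = butter_lowpass_zero_lag(chan, rate=markers.rate,
                                                   cutoff=cutoff, order=order, axis=0)
    return MarkerTrajectorySet(labels=list(markers.labels), positions=pos,
                               rate=markers.rate, events=dict(markers.events))


def normalize_time(trajectory: JointAngleTrajectory, phases: PhaseAnnotation,
                   n_points: int = 100) -> JointAngleTrajectory:
    """Resample a trajectory onto the phase-normalized [0, 1] grid.

    The grid is ``n_points`` uniform samples (default 100, i.e. 99 steps
    plus the endpoint); each phase maps linearly onto one third of the
    axis, so the phase boundaries land exactly on 1/3 and 2/3. Angle values
    are linearly interpolated at the warped sample positions.
    """
    if n_points < 4:
        raise ValidationError("n_points must be at least 4")
    n = trajectory.n_samples
    (s0, e0), (s1, e1), (s2, e2) = phases.phases
    if e2 > n:
        raise ValidationError("phase annotation extends past the trajectory")
    grid = np.linspace(0.0, 1.0, n_points)
    # piecewise-linear warp: normalized time knots -> sample positions
    knots_t = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    knots_f = np.array([s0, s1, s2, e2 - 1], dtype=float)
    sample_pos = np.interp(grid, knots_t, knots_f)
    base = np.arange(n, dtype=float)
    angles = {k: np.interp(sample_pos, base, v) for k, v in trajectory.angles.items()}
    return replace(trajectory, angles=angles, time=None, normalized_time=grid,
                   gimbal_flags=None)


def rom(trajectory: JointAngleTrajectory, angle_name: str) -> float:
    """Range of motion: max − min of the named angle over the task (deg)."""
    if angle_name not in trajectory.angles:
        raise ValidationError(
            f"unknown angle {angle_name!r}; have {sorted(trajectory.angles)}"
        )
    trace = trajectory.angles[angle_name]
    finite = trace[np.isfinite(trace)]
    if finite.size == 0:
        raise ValidationError("angle trace has no finite samples")
    return float(finite.max() - finite.min())


def _common_grid(trajectories):
    grids = []
    for t in trajectories:
        if t.normalized_time is None:
            raise ValidationError("trajectories must be time-normalized first")
        grids.append(t.normalized_time)
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValidationError("trajectories are not on a common normalized grid")
    return grids[0]


def trial_mean_sd(trajectories) -> tuple[dict, dict]:
    """Pointwise mean and sample SD across repeated trials.

    Returns ``(mean, sd)`` dicts keyed by angle name, over the angles all
    trials share. Requires at least two trials on a common grid.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise ValidationError("need at least two trials for a mean/SD summary")
    _common_grid(trajectories)
    names = set(trajectories[0].angles)
    for t in trajectories[1:]:
        names &= set(t.angles)
    mean, sd = {}, {}
    for name in sorted(names):
        stack = np.vstack([t.angles[name] for t in trajectories])
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=1)
    return mean, sd


def rmsd_between(trace_a, trace_b) -> float:
    """Root-mean-square difference between two traces on a common grid (deg)."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"trace grids differ: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    if not np.any(ok):
        raise ValidationError("no overlapping finite samples")
    return float(np.sqrt(np.mean((a[ok] - b[ok]) ** 2)))
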