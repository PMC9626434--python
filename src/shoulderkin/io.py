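"""Plain-text interchange formats.

TRC marker trajectories (OpenSim-style tab-separated), landmark sets as
JSON or CSV, shoulder models as JSON, phase-event sidecars and cohort
tables as CSV. All positions are metres in a right-handed, Y-up frame.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import LandmarkSet, ShoulderModel
from .directk import MarkerTrajectorySet
from .exceptions import ValidationError
from .signal_prep import PhaseAnnotation

__all__ = [
    "write_trc", "read_trc",
    "write_landmarks_json", "read_landmarks_json",
    "write_landmarks_csv", "read_landmarks_csv",
    "write_model_json", "read_model_json",
    "write_events_csv", "read_events_csv",
    "write_cohort_csv", "read_cohort_csv",
]


def write_trc(markers: MarkerTrajectorySet, path, name: str | None = None):
    """Write an OpenSim-style .trc file (tab-separated, metres)."""
    path = Path(path)
    n_frames, n_markers = markers.positions.shape[:2]
    rate = markers.rate
    lines = []
    lines.append(f"PathFileType\t4\t(X/Y/Z)\t{name or path.name}")
    lines.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    lines.append(f"{rate:.2f}\t{rate:.2f}\t{n_frames}\t{n_markers}\tm\t"
                 f"{rate:.2f}\t1\t{n_frames}")
    head = ["Frame#", "Time"]
    for label in markers.labels:
        head += [label, "", ""]
    lines.append("\t".join(head))
    sub = ["", ""]
    for i in range(1, n_markers + 1):
        sub += [f"X{i}", f"Y{i}", f"Z{i}"]
    lines.append("\t".join(sub))
    lines.append("")
    times = markers.times
    for f in range(n_frames):
        row = [str(f + 1), f"{times[f]:.5f}"]
        for m in range(n_markers):
            for c in range(3):
                v = markers.positions[f, m, c]
                row.append("" if not np.isfinite(v) else f"{v:.8f}")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path) -> MarkerTrajectorySet:
    text = Path(path).read_text().splitlines()
    if len(text) < 6:
        raise ValidationError("not a TRC file: too few lines")
    meta_names = text[1].split("\t")
    meta_vals = text[2].split("\t")
    meta = dict(zip(meta_names, meta_vals))
    rate = float(meta["DataRate"])
    n_markers = int(meta["NumMarkers"])
    labels = [x for x in text[3].split("\t")[2:] if x][:n_markers]
    if len(labels) != n_markers:
        raise ValidationError("TRC header marker labels do not match NumMarkers")
    rows = []
    for line in text[5:]:
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip():
            continue
        vals = [float(v) if v.strip() else np.nan for v in parts[2:2 + 3 * n_markers]]
        if len(vals) < 3 * n_markers:
            vals += [np.nan] * (3 * n_markers - len(vals))
        rows.append(vals)
    positions = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    return MarkerTrajectorySet(labels=labels, positions=positions, rate=rate)


def write_landmarks_json(landmarks: LandmarkSet, path, gh_centre=None):
    doc = {
        "units": "m",
        "frame": "right-handed, Y up, X anterior, Z right",
        "landmarks": {k: list(map(float, v)) for k, v in landmarks.items()},
    }
    if gh_centre is not None:
        doc["gh_centre"] = list(map(float, np.asarray(gh_centre, dtype=float)))
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_landmarks_json(path):
    doc = json.loads(Path(path).read_text())
    lm = LandmarkSet(doc["landmarks"])
    gh = np.asarray(doc["gh_centre"], dtype=float) if "gh_centre" in doc else None
    return lm, gh


def write_landmarks_csv(landmarks: LandmarkSet, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name, p in landmarks.items():
            w.writerow([name, f"{p[0]:.9f}", f"{p[1]:.9f}", f"{p[2]:.9f}"])


def read_landmarks_csv(path) -> LandmarkSet:
    lm = LandmarkSet()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lm[row["name"]] = [float(row["x"]), float(row["y"]), float(row["z"])]
    return lm


def write_model_json(model: ShoulderModel, path):
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model_json(path) -> ShoulderModel:
    return ShoulderModel.from_dict(json.loads(Path(path).read_text()))


def write_events_csv(path, phases: PhaseAnnotation, trial: int = 0, append: bool = False):
    mode = "a" if append else "w"
    new = not (append and Path(path).exists())
    with open(path, mode, newline="") as fh:
        w = csv.writer(fh)
        if new or not append:
            w.writerow(["trial", "phase", "start_frame", "end_frame"])
        for k, (s, e) in enumerate(phases.phases, start=1):
            w.writerow([trial, k, s, e])


def read_events_csv(path) -> dict:
    """Events per trial: {trial: PhaseAnnotation}."""
    per_trial: dict = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            per_trial.setdefault(int(row["trial"]), []).append(
                (int(row["phase"]), int(row["start_frame"]), int(row["end_frame"]))
            )
    out = {}
    for trial, rows in per_trial.items():
        rows.sort()
        out[trial] = PhaseAnnotation(tuple((s, e) for _, s, e in rows))
    return out


def write_cohort_csv(table: pd.DataFrame, path):
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
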