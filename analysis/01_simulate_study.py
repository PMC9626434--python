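#!/usr/bin/env python
"""Materialize one participant's worth of in-silico study inputs.

Generates the participant's anatomy (landmark set + truth model), the
scaled-generic counterpart, and two noisy trials of each planar task as
TRC files with phase-event sidecars — the same file formats an
experimental study would hand to the kinematics stage. Raw trials are
bulky and fully regenerable, so they go under scratch/study_inputs/;
the later scripts read them from there and put only compact result
tables under results/.
"""

from pathlib import Path

from shoulderkin.anatomy import anatomical_errors
from shoulderkin.io import (
    write_events_csv,
    write_landmarks_json,
    write_model_json,
    write_trc,
)
from shoulderkin.synth import (
    AnatomyParams,
    NoiseModel,
    TaskProgram,
    generate_anatomy,
    generate_task,
    make_scaled_generic,
    synthesize_markers,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "study_inputs"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    params = AnatomyParams(sex_code=1.1, height_cm=167.0, mass_kg=60.0)
    landmarks, gh, truth = generate_anatomy(params, seed=SEED)
    sg = make_scaled_generic(truth, (0.5, 1.0, -1.5))

    write_landmarks_json(landmarks, OUT / "landmarks.json", gh_centre=gh)
    write_model_json(truth, OUT / "model_truth.json")
    write_model_json(sg, OUT / "model_scaled_generic.json")
    errs = anatomical_errors(truth, sg)
    print(f"participant: {params.sex_code=}, {params.bmi:.1f} kg/m^2")
    print(f"injected anatomical errors (truth - SG, cm): "
          f"clavicle {errs.delta_clavicle:+.2f}, scapula {errs.delta_scapula:+.2f}, "
          f"humerus {errs.delta_humerus:+.2f}")

    for task in ("AA", "FE", "IER"):
        q, phases = generate_task(TaskProgram(task))
        for trial in range(2):  # two sample trials per task on disk
            noise = NoiseModel(marker_sd=0.005, artifact_amplitude=0.005,
                               seed=SEED * 100 + trial)
            markers = synthesize_markers(truth, q, phases, noise=noise)
            stem = f"{task.lower()}_trial{trial}"
            write_trc(markers, OUT / f"{stem}.trc")
            write_events_csv(OUT / f"{stem}_events.csv", phases, trial=trial)
        print(f"{task}: wrote 2 sample trials "
              f"({q.shape[0]} frames at 200 Hz, phases {phases.phases})")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
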