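"""The synthetic study generator: determinism, task programs, marker
synthesis, controlled anatomical errors and cohort construction."""

import numpy as np
import pytest

from shoulderkin.anatomy import anatomical_errors
from shoulderkin.directk import ClusterCalibration, direct_ghj_angles
from shoulderkin.exceptions import ValidationError
from shoulderkin.ik import ik_solve_trajectory
from shoulderkin.signal_prep import MAIN_ANGLE, JointAngleTrajectory, normalize_time, rom
from shoulderkin.synth import (
    AnatomyParams,
    NoiseModel,
    TaskProgram,
    generate_anatomy,
    generate_cohort,
    generate_task,
    make_scaled_generic,
    synthesize_markers,
)


class TestGenerateAnatomy:
    def test_same_seed_and_params_reproduce_identical_models(self):
        p = AnatomyParams(sex_code=1.1, height_cm=160.0, mass_kg=55.0)
        a = generate_anatomy(p, seed=7)
        b = generate_anatomy(p, seed=7)
        for n in a[0]:
            assert np.array_equal(a[0][n], b[0][n])
        assert a[2].inter_joint_distances() == b[2].inter_joint_distances()

    def test_doubling_humerus_length_doubles_gh_elbow_distance(self):
        p1 = AnatomyParams(humerus_length=0.28)
        p2 = AnatomyParams(humerus_length=0.35)
        m1 = generate_anatomy(p1, seed=0, shape_jitter_sd=0.0)[2]
        m2 = generate_anatomy(p2, seed=0, shape_jitter_sd=0.0)[2]
        r = m2.inter_joint_distances()["humerus"] / m1.inter_joint_distances()["humerus"]
        assert r == pytest.approx(0.35 / 0.28, abs=1e-9)

    def test_model_invariants_hold(self, truth_model):
        assert truth_model.dof_count == 8
        assert truth_model.provenance == "synthetic_truth"
        for j in truth_model.joints:
            # aligned template: rest orientations are exactly identity
            assert np.allclose(j.rest_rotation, np.eye(3), atol=1e-12)

    def test_implausible_anthropometrics_rejected(self):
        with pytest.raises(ValidationError):
            AnatomyParams(height_cm=80.0)
        with pytest.raises(ValidationError):
            AnatomyParams(humerus_length=0.5).resolved_lengths()
        with pytest.raises(ValidationError):
            AnatomyParams(sex_code=0.0)


class TestGenerateTask:
    def test_requested_peak_is_reached_exactly_in_hold_phase(self):
        q, phases = generate_task(TaskProgram("AA", peak=90.0, st_to_gh_ratio=0.0))
        ghj_x = q[:, 6]
        assert ghj_x.max() == pytest.approx(90.0, abs=1e-12)
        (s1, e1) = phases.phases[1]
        assert np.allclose(ghj_x[s1:e1], 90.0)
        assert ghj_x[0] == 0.0 and abs(ghj_x[-1]) < 1e-6

    def test_phase_boundaries_at_default_rate(self):
        _, phases = generate_task(TaskProgram("AA"))
        assert phases.phases == ((0, 400), (400, 800), (800, 1200))

    def test_zero_peak_gives_constant_neutral(self):
        q, _ = generate_task(TaskProgram("FE", peak=0.0))
        assert np.allclose(q, 0.0)

    def test_ier_ramps_external_to_internal(self):
        q, phases = generate_task(TaskProgram("IER", peak=40.0))
        y = q[:, 5]
        assert y[0] == pytest.approx(-40.0)
        assert y[phases.phases[1][0]] == pytest.approx(40.0)
        assert y[-1] == pytest.approx(-40.0, abs=1e-4)


class TestSynthesizeMarkers:
    def test_same_seed_reproduces_identical_trc_bytes(self, truth_model, tmp_path):
        from shoulderkin.io import write_trc

        q, phases = generate_task(TaskProgram("AA", phase_duration=0.25))
        paths = []
        for k in (1, 2):
            mk = synthesize_markers(truth_model, q, phases,
                                    noise=NoiseModel(seed=99))
            p = tmp_path / f"trial{k}.trc"
            write_trc(mk, p, name="trial.trc")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_noiseless_pipeline_round_trip(self, truth_model, aa_trial):
        """Markers synthesized from a program are inverted by both IK and
        DirectK to the programmed angles."""
        q, _, markers = aa_trial
        calib = ClusterCalibration.from_model(truth_model)
        dk = direct_ghj_angles(markers, calib)
        assert np.nanmax(np.abs(dk.angles - q[:, [5, 6, 7]])) < 1e-3
        res = ik_solve_trajectory(truth_model, markers, stride=60)
        assert np.abs(res.q_trajectory - q[::60]).max() < 1e-3


class TestMakeScaledGeneric:
    def test_zero_spec_matches_inter_joint_distances(self, truth_model):
        sg = make_scaled_generic(truth_model, (0.0, 0.0, 0.0))
        assert np.allclose(anatomical_errors(truth_model, sg).as_array(), 0.0,
                           atol=1e-9)
        assert sg.provenance == "scaled_generic"

    def test_prescribed_errors_are_hit_exactly(self, truth_model):
        spec = (0.5, 1.0, -1.5)
        sg = make_scaled_generic(truth_model, spec)
        assert np.allclose(anatomical_errors(truth_model, sg).as_array(), spec,
                           atol=1e-6)
        assert sg.dof_count == 8

    def test_infeasible_spec_rejected(self, truth_model):
        with pytest.raises(ValidationError):
            make_scaled_generic(truth_model, (0.0, 50.0, 0.0))


class TestGenerateCohort:
    def test_linear_mode_zero_noise_recovers_coefficients(self):
        beta = np.array([2.0, -1.0, 0.3, 1.0, -2.0, 0.5])
        from shoulderkin.agreement import PREDICTORS, fit_delta_rom_regression

        _, table = generate_cohort(n=30, coefficient_vector=beta, noise_sd=0.0,
                                   seed=21, tasks=("FE",))
        res = fit_delta_rom_regression(table, "FE")
        for name, b in zip(["intercept", *PREDICTORS], beta):
            assert res.coefficients[name] == pytest.approx(b, abs=1e-8)

    def test_seeded_cohort_reproducible(self):
        _, t1 = generate_cohort(n=12, seed=5)
        _, t2 = generate_cohort(n=12, seed=5)
        assert t1.equals(t2)

    def test_sex_ratio_and_ranges(self):
        bundles, table = generate_cohort(n=12, seed=8, tasks=("AA",))
        sexes = [b.params.sex_code for b in bundles]
        assert sexes.count(1.1) == 8 and sexes.count(1.0) == 4
        assert np.all(np.abs(table[["delta_clavicle", "delta_scapula",
                                    "delta_humerus"]].to_numpy()) <= 3.0)

    def test_small_cohort_rejected_by_default(self):
        with pytest.raises(ValidationError):
            generate_cohort(n=5)

    def test_mechanistic_larger_scapula_error_larger_delta_rom(self, truth_model):
        """Injecting a larger scapular inter-joint error produces a larger
        kinematic ROM deviation on the same trial (paired comparison)."""
        from shoulderkin.pipeline import mechanistic_delta_rom

        small = make_scaled_generic(truth_model, (0.0, 0.5, 0.0))
        large = make_scaled_generic(truth_model, (0.0, 2.5, 0.0))
        d_small = mechanistic_delta_rom(truth_model, small, "AA", ik_stride=40,
                                        phase_duration=0.5)
        d_large = mechanistic_delta_rom(truth_model, large, "AA", ik_stride=40,
                                        phase_duration=0.5)
        assert abs(d_large) > abs(d_small)


def test_full_loop_identity(truth_model):
    """generate → synthesize (noiseless) → IK with the truth model →
    normalize → ROM equals the programmed peak within 0.05°."""
    program = TaskProgram("AA")
    q, phases = generate_task(program)
    markers = synthesize_markers(truth_model, q, phases, noise=None)
    res = ik_solve_trajectory(truth_model, markers, stride=20)
    traj = JointAngleTrajectory(
        task="AA", source="truth",
        angles={name: col for name, col in zip(
            ("ghj_y", "ghj_x", "ghj_z"),
            res.ghj_cardan(truth_model).T)},
    )
    from shoulderkin.pipeline import _strided_phases

    ph = _strided_phases(phases, 20, len(res.q_trajectory))
    norm = normalize_time(traj, ph, n_points=100)
    assert rom(norm, MAIN_ANGLE["AA"]) == pytest.approx(
        program.resolved_peak, abs=0.05)
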