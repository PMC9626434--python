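"""Forward kinematics of the chain and global-optimization inverse
kinematics: exact recovery, joint congruency, residual behaviour."""

import numpy as np
import pytest

from shoulderkin.anatomy import thorax_cs
from shoulderkin.exceptions import ValidationError
from shoulderkin.ik import (
    _FKEngine,
    forward_kinematics,
    ik_solve_frame,
    ik_solve_trajectory,
    marker_rmsd,
    segment_poses,
    thoracohumeral_elevation,
)
from shoulderkin.synth import NoiseModel, TaskProgram, generate_task, synthesize_markers


@pytest.fixture(scope="module")
def neutral_pose(truth_anatomy):
    landmarks, _, _ = truth_anatomy
    return thorax_cs(landmarks)


class TestForwardKinematics:
    def test_neutral_q_reproduces_assembly_markers(self, truth_model, neutral_pose,
                                                   truth_anatomy):
        landmarks, _, _ = truth_anatomy
        fk = forward_kinematics(truth_model, np.zeros(8), neutral_pose)
        for name in ("C7", "IJ", "EL", "EM", "AC"):
            assert np.allclose(fk[name], landmarks[name], atol=1e-12)

    def test_ghj_rotation_leaves_proximal_markers_fixed(self, truth_model, neutral_pose):
        fk0 = forward_kinematics(truth_model, np.zeros(8), neutral_pose)
        q = np.zeros(8)
        q[6] = 45.0  # pure GHJ abduction
        fk1 = forward_kinematics(truth_model, q, neutral_pose)
        for name in ("C7", "T8", "IJ", "PX", "AC", "SSP1", "SSP2", "SSP3"):
            assert np.allclose(fk0[name], fk1[name], atol=1e-12)
        assert np.linalg.norm(fk0["EL"] - fk1["EL"]) > 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_joint_congruency_for_arbitrary_q(self, truth_model, neutral_pose, seed):
        """Both sides of every joint reconstruct the same world centre: no
        distraction or co-penetration for any coordinates."""
        rng = np.random.default_rng(seed)
        q = rng.uniform(-60, 60, size=8)
        poses = segment_poses(truth_model, q, neutral_pose)
        for joint in truth_model.joints:
            wp = poses[joint.parent].transform(joint.centre_in_parent)
            wc = poses[joint.child].transform(joint.centre_in_child)
            assert np.allclose(wp, wc, atol=1e-12)

    def test_invalid_q_rejected(self, truth_model, neutral_pose):
        with pytest.raises(ValidationError):
            forward_kinematics(truth_model, np.zeros(7), neutral_pose)
        bad = np.zeros(8)
        bad[3] = np.nan
        with pytest.raises(ValidationError):
            forward_kinematics(truth_model, bad, neutral_pose)


class TestMarkerRmsd:
    def test_identical_sets_give_zero(self):
        obs = {"A": np.zeros(3), "B": np.ones(3)}
        assert marker_rmsd(obs, obs) == 0.0

    def test_single_marker_offset(self):
        a = {"A": np.zeros(3)}
        b = {"A": np.array([0.03, 0.0, 0.0])}
        assert marker_rmsd(a, b) == pytest.approx(0.03)

    def test_two_marker_hand_computation(self):
        a = {"A": np.zeros(3), "B": np.zeros(3)}
        b = {"A": np.array([0.03, 0, 0]), "B": np.array([0, 0.04, 0])}
        # sqrt((3^2 + 4^2)/2) cm = 3.5355... cm
        assert marker_rmsd(a, b) == pytest.approx(0.035355, abs=1e-6)

    def test_no_common_markers_rejected(self):
        with pytest.raises(ValidationError):
            marker_rmsd({"A": np.zeros(3)}, {"B": np.zeros(3)})


class TestIKFrame:
    def test_round_trip_recovery_from_neutral_start(self, truth_model, neutral_pose):
        q_true = np.array([3.0, 8.0, -4.0, 15.0, 5.0, 10.0, 40.0, -6.0])
        observed = forward_kinematics(truth_model, q_true, neutral_pose)
        sol = ik_solve_frame(truth_model, observed)
        assert np.allclose(sol.q, q_true, atol=1e-3)
        assert sol.rms < 1e-9

    def test_zero_weights_rejected(self, truth_model, neutral_pose):
        observed = forward_kinematics(truth_model, np.zeros(8), neutral_pose)
        weights = {m: 0.0 for m in observed}
        with pytest.raises(ValidationError):
            ik_solve_frame(truth_model, observed, weights=weights)

    def test_objective_not_worse_than_init(self, truth_model, neutral_pose):
        """The optimizer never returns a q with a larger residual than its
        starting point."""
        q_true = np.array([2.0, 6.0, -2.0, 10.0, 3.0, 5.0, 30.0, -4.0])
        observed = forward_kinematics(truth_model, q_true, neutral_pose)
        rng = np.random.default_rng(0)
        observed = {k: v + rng.normal(0, 0.004, 3) for k, v in observed.items()}

        def objective(q):
            virtual = forward_kinematics(truth_model, q, neutral_pose)
            return sum(np.sum((virtual[m] - observed[m]) ** 2) for m in observed)

        q_init = np.zeros(8)
        sol = ik_solve_frame(truth_model, observed, q_init=q_init, thorax_pose=neutral_pose)
        assert objective(sol.q) <= objective(q_init) + 1e-15

    def test_noisy_markers_stay_within_rms_tolerance(self, truth_model, neutral_pose):
        """5 mm isotropic noise leaves the residual far below the 2.5 cm
        acceptance threshold on marker RMSd."""
        q_true = np.array([1.0, 5.0, 0.0, 10.0, 0.0, 0.0, 45.0, 0.0])
        observed = forward_kinematics(truth_model, q_true, neutral_pose)
        rng = np.random.default_rng(42)
        observed = {k: v + rng.normal(0, 0.005, 3) for k, v in observed.items()}
        sol = ik_solve_frame(truth_model, observed)
        assert sol.rms <= 0.025


class TestIKTrajectory:
    def test_noiseless_trial_recovers_programmed_angles(self, truth_model, aa_trial):
        q, _, markers = aa_trial
        res = ik_solve_trajectory(truth_model, markers, stride=40)
        assert res.valid.all()
        diff = res.q_trajectory - q[::40]
        assert np.sqrt(np.mean(diff[:, 5:] ** 2)) <= 0.01
        assert res.global_rmsd < 1e-9

    def test_model_mismatch_gives_nonzero_angle_differences(self, truth_model, aa_trial):
        from shoulderkin.synth import make_scaled_generic

        _, _, markers = aa_trial
        sg = make_scaled_generic(truth_model, (1.0, 2.0, -1.0))
        res_truth = ik_solve_trajectory(truth_model, markers, stride=60)
        res_sg = ik_solve_trajectory(sg, markers, stride=60)
        ghj_t = res_truth.ghj_cardan(truth_model)
        ghj_s = res_sg.ghj_cardan(sg)
        assert res_sg.global_rmsd > 1e-4
        assert np.nanmax(np.abs(ghj_t - ghj_s)) > 0.5

    def test_empty_trajectory_rejected(self, truth_model):
        from shoulderkin.directk import MarkerTrajectorySet

        empty = MarkerTrajectorySet(labels=["A"], positions=np.zeros((0, 1, 3)), rate=200.0)
        with pytest.raises(ValidationError):
            ik_solve_trajectory(truth_model, empty)


class TestElevation:
    def test_default_aa_program_reaches_shoulder_level(self, truth_model):
        q, _ = generate_task(TaskProgram("AA"))
        elev = thoracohumeral_elevation(truth_model, q)
        assert elev.max() == pytest.approx(90.0, abs=1e-9)
        assert elev[0] == pytest.approx(0.0, abs=1e-9)

    def test_artifact_increases_ik_residual(self, truth_model):
        """A 5 mm scapular skin artifact strictly raises the IK marker
        residual over the artifact-free trial."""
        program = TaskProgram("AA", phase_duration=0.5)
        q, phases = generate_task(program)
        clean = synthesize_markers(truth_model, q, phases, noise=None)
        arty = synthesize_markers(
            truth_model, q, phases,
            noise=NoiseModel(marker_sd=0.0, artifact_amplitude=0.005),
        )
        r_clean = ik_solve_trajectory(truth_model, clean, stride=10)
        r_arty = ik_solve_trajectory(truth_model, arty, stride=10)
        assert r_arty.global_rmsd > r_clean.global_rmsd
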