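"""Segment frames, sphere fitting, model assembly, scaling and
anatomical-error accounting."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from shoulderkin.anatomy import (
    LandmarkSet,
    anatomical_errors,
    assemble_model,
    clavicle_cs,
    fit_sphere,
    humerus_cs,
    scale_generic,
    scapula_cs,
    thorax_cs,
)
from shoulderkin.exceptions import (
    DegenerateGeometryError,
    MissingLandmarkError,
    ValidationError,
)
from shoulderkin.ik import forward_kinematics
from shoulderkin.synth import _template_landmarks, make_scaled_generic


@pytest.fixture(scope="module")
def template_landmarks():
    lm, gh = _template_landmarks(0.15, 0.04, 0.30)
    lm = LandmarkSet(lm)
    lm["GH"] = gh  # expose the GHJ centre as a named landmark for the builders
    return lm, gh


class TestCoordinateSystems:
    def test_axis_aligned_thorax_gives_identity(self, template_landmarks):
        lm, _ = template_landmarks
        cs = thorax_cs(lm)
        assert np.allclose(cs.axes, np.eye(3), atol=1e-12)
        assert np.allclose(cs.origin, lm["IJ"])

    @pytest.mark.parametrize("builder", [thorax_cs, clavicle_cs, scapula_cs, humerus_cs])
    def test_axes_are_proper_rotations(self, builder, template_landmarks):
        lm, _ = template_landmarks
        cs = builder(lm)
        assert np.allclose(cs.axes.T @ cs.axes, np.eye(3), atol=1e-12)
        assert np.linalg.det(cs.axes) == pytest.approx(1.0)

    @pytest.mark.parametrize("builder", [thorax_cs, clavicle_cs, scapula_cs, humerus_cs])
    def test_rigid_equivariance(self, builder, template_landmarks):
        """Rotating + translating the landmarks rotates the axes and moves
        the origin accordingly."""
        lm, _ = template_landmarks
        Q = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        t = np.array([0.2, -0.1, 0.35])
        moved = lm.transformed(Q, t)
        cs0 = builder(lm)
        cs1 = builder(moved)
        assert np.allclose(cs1.axes, Q @ cs0.axes, atol=1e-9)
        assert np.allclose(cs1.origin, Q @ cs0.origin + t, atol=1e-9)

    def test_scapula_z_along_spine(self):
        lm = LandmarkSet({"AA": [0, 0, 0], "TS": [-0.1, 0, 0], "AI": [-0.1, -0.12, 0]})
        cs = scapula_cs(lm)
        assert np.allclose(cs.axes[:, 2], [1.0, 0.0, 0.0], atol=1e-12)

    def test_thorax_y_points_cranially(self, template_landmarks):
        lm, _ = template_landmarks
        assert thorax_cs(lm).axes[1, 1] > 0.9

    def test_missing_landmark_raises_named_error(self, template_landmarks):
        lm, _ = template_landmarks
        partial = LandmarkSet({k: v for k, v in lm.items() if k != "AI"})
        with pytest.raises(MissingLandmarkError, match="AI"):
            scapula_cs(partial)

    def test_collinear_landmarks_raise(self):
        lm = LandmarkSet({"AA": [0, 0, 0], "TS": [-0.1, 0, 0], "AI": [-0.2, 0, 0]})
        with pytest.raises(DegenerateGeometryError):
            scapula_cs(lm)


class TestFitSphere:
    @staticmethod
    def _sphere_points(centre, radius, n, rng, noise_sd=0.0):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = centre + radius * v
        if noise_sd:
            pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
        return pts

    def test_exact_points_recover_sphere(self, rng):
        centre = np.array([1.0, 2.0, 3.0])
        pts = self._sphere_points(centre, 0.025, 50, rng)
        c, r, resid = fit_sphere(pts)
        assert np.allclose(c, centre, atol=1e-9)
        assert r == pytest.approx(0.025, abs=1e-9)
        assert resid < 1e-9

    def test_noisy_fit_matches_brute_force(self, rng):
        """Gauss-Newton refinement agrees with a direct nonlinear
        minimization of the same objective, and the centre error stays
        below the noise scale."""
        centre = np.array([0.1, -0.2, 0.05])
        pts = self._sphere_points(centre, 0.025, 200, rng, noise_sd=5e-4)
        c, r, _ = fit_sphere(pts)
        assert np.linalg.norm(c - centre) < 5e-4

        def objective(x):
            return np.sum((np.linalg.norm(pts - x[:3], axis=1) - x[3]) ** 2)

        brute = minimize(objective, np.r_[pts.mean(axis=0), 0.02], method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert np.allclose(c, brute.x[:3], atol=1e-6)
        assert r == pytest.approx(brute.x[3], abs=1e-6)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.3, 0.7, 0]])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.eye(3) * 0.1)


class TestAssembleModel:
    def test_eight_degrees_of_freedom(self, truth_model):
        assert truth_model.dof_count == 8
        assert [j.dof_count for j in truth_model.joints] == [2, 3, 3]

    def test_neutral_forward_kinematics_reproduces_landmarks(self, template_landmarks):
        """Assembly then FK at q = 0 (thorax pose from the source landmarks)
        is a lossless round trip."""
        lm, gh = template_landmarks
        Q = Rotation.from_rotvec([0.2, 0.4, -0.3]).as_matrix()
        t = np.array([0.5, 1.2, -0.7])
        world = lm.transformed(Q, t)
        model = assemble_model(world, Q @ gh + t)
        fk = forward_kinematics(model, np.zeros(8), thorax_cs(world),
                                include_landmarks=True)
        for seg in model.segments.values():
            for name in seg.local_landmarks:
                key = f"{seg.name}:{name}"
                if name in world:
                    assert np.allclose(fk[key], world[name], atol=1e-9), key

    def test_missing_gh_centre_rejected(self, template_landmarks):
        lm, _ = template_landmarks
        with pytest.raises(ValidationError):
            assemble_model(lm, [np.nan, 0.0, 0.0])


class TestScaleGeneric:
    def test_identity_scaling(self, template_model, template_landmarks):
        lm, gh = template_landmarks
        scaled, spec = scale_generic(template_model, lm, gh)
        assert spec.clavicle_ratio == pytest.approx(1.0, abs=1e-9)
        assert spec.humerus_ratio == pytest.approx(1.0, abs=1e-9)
        assert spec.scapula_ac_ts_ratio == pytest.approx(1.0, abs=1e-6)
        assert spec.scapula_ai_ts_ratio == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(spec.thorax_ratios, 1.0, atol=1e-9)
        for a, b in zip(scaled.inter_joint_distances().values(),
                        template_model.inter_joint_distances().values()):
            assert a == pytest.approx(b, abs=1e-9)

    def test_humerus_length_ratio(self, template_model):
        lm, gh = _template_landmarks(0.15, 0.04, 0.33)
        scaled, spec = scale_generic(template_model, lm, gh)
        assert spec.humerus_ratio == pytest.approx(1.1, abs=1e-9)
        assert scaled.inter_joint_distances()["humerus"] == pytest.approx(0.33, abs=1e-9)

    def test_scapula_measurements_match_target(self, template_model):
        lm, gh = _template_landmarks(0.16, 0.05, 0.31)
        scaled, _ = scale_generic(template_model, lm, gh)
        loc = scaled.segments["scapula"].local_landmarks
        assert np.linalg.norm(loc["AC"] - loc["TS"]) == pytest.approx(
            np.linalg.norm(lm["AC"] - lm["TS"]), abs=1e-6)
        assert np.linalg.norm(loc["AI"] - loc["TS"]) == pytest.approx(
            np.linalg.norm(lm["AI"] - lm["TS"]), abs=1e-6)


class TestAnatomicalErrors:
    def test_identical_models_have_zero_errors(self, truth_model):
        e = anatomical_errors(truth_model, truth_model)
        assert np.allclose(e.as_array(), 0.0)

    def test_controlled_humerus_elongation(self, truth_model):
        longer = make_scaled_generic(truth_model, (0.0, 0.0, -2.0))
        e = anatomical_errors(truth_model, longer)
        assert e.delta_humerus == pytest.approx(-2.0, abs=1e-6)
        assert e.delta_clavicle == pytest.approx(0.0, abs=1e-6)
        assert e.delta_scapula == pytest.approx(0.0, abs=1e-6)

    def test_antisymmetry(self, truth_model):
        other = make_scaled_generic(truth_model, (0.5, -1.0, 1.5))
        ab = anatomical_errors(truth_model, other).as_array()
        ba = anatomical_errors(other, truth_model).as_array()
        assert np.allclose(ab, -ba, atol=1e-12)
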