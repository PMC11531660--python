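"""Tests for the per-specimen axis constructions."""

import numpy as np
import pytest

from elbowaxis import geometry as geo
from elbowaxis.axes import (BoneMesh, LandmarkSet, distal_humeral_axis,
                            epicondylar_axis, true_fe_axis)
from elbowaxis.errors import DegenerateInputError, LandmarkError
from elbowaxis.synthetic import SyntheticSpec, generate_specimen, solve_ground_truth

from .oracles import random_rigid_transform
from .test_geometry import circle_points


def landmarks_with(groove=None, medial=None, lateral=None, zrange=(0.0, 40.0)):
    groove = groove if groove is not None else circle_points((0, 0, -20), 9.0, (1, 0, 0))
    medial = medial if medial is not None else np.tile([30.0, 0, -20], (3, 1))
    lateral = lateral if lateral is not None else np.tile([-30.0, 0, -20], (3, 1))
    return LandmarkSet(medial_picks=medial, lateral_picks=lateral,
                       groove_points=groove, shaft_zrange=zrange)


class TestEpicondylarAxis:
    def test_identical_picks_give_exact_axis(self):
        lm = landmarks_with()
        line, medial, lateral = epicondylar_axis(lm)
        assert np.allclose(medial, (30, 0, -20))
        assert np.allclose(lateral, (-30, 0, -20))
        assert np.allclose(line.direction, (1, 0, 0))

    def test_pick_order_is_irrelevant(self, rng):
        picks_m = np.array([[30, 1, -20], [29, -1, -21], [31, 0, -19.0]])
        picks_l = np.array([[-30, 1, -20], [-29, -1, -21], [-31, 0, -19.0]])
        lm1 = landmarks_with(medial=picks_m, lateral=picks_l)
        lm2 = landmarks_with(medial=picks_m[::-1], lateral=picks_l[[1, 2, 0]])
        l1, m1, _ = epicondylar_axis(lm1)
        l2, m2, _ = epicondylar_axis(lm2)
        assert np.allclose(m1, m2)
        assert np.allclose(l1.direction, l2.direction)

    def test_coincident_means_raise(self):
        same = np.tile([1.0, 2.0, 3.0], (3, 1))
        with pytest.raises(DegenerateInputError):
            epicondylar_axis(landmarks_with(medial=same, lateral=same))

    def test_jittered_picks_recover_apex_within_sampling_bound(self):
        sigma = 0.5
        errs = []
        for seed in range(30):
            bone, lm, gt = generate_specimen(
                SyntheticSpec(landmark_jitter_mm=sigma, seed=seed,
                              n_theta=49, n_profile=48))
            _, medial, lateral = epicondylar_axis(lm)
            errs.append(np.linalg.norm(medial - gt.medial_epicondyle))
            errs.append(np.linalg.norm(lateral - gt.lateral_epicondyle))
        # mean of 3 picks: per-axis SE sigma/sqrt(3); 3D error bounded by 3 SE
        assert np.median(errs) < 3 * sigma / np.sqrt(3)


class TestDistalHumeralAxis:
    def _cylinder_bone(self, spec=None):
        from elbowaxis.synthetic import _shaft_mesh
        spec = spec or SyntheticSpec()
        return BoneMesh(_shaft_mesh(spec), specimen_id="shaft", side="right")

    def test_straight_elliptical_shaft_recovers_axis(self):
        spec = SyntheticSpec()
        bone = self._cylinder_bone(spec)
        groove_hint = circle_points((0, 0, 0), 5.0, (1, 0, 0))  # distal of the shaft
        lm = landmarks_with(groove=groove_hint, zrange=(-30.0, 30.0))
        line, ellipses = distal_humeral_axis(bone, lm)
        assert geo.angle_deg(line.direction, (0, 0, 1)) < 1e-3
        assert len(ellipses) == 5
        for e in ellipses:
            assert abs(e.a - spec.shaft_radii[0]) < 0.02 * spec.shaft_radii[0]
            assert abs(e.b - spec.shaft_radii[1]) < 0.02 * spec.shaft_radii[1]

    def test_rigidly_transformed_shaft_gives_transformed_axis(self, rng):
        bone = self._cylinder_bone()
        groove_hint = circle_points((0, 0, 0), 5.0, (1, 0, 0))
        lm = landmarks_with(groove=groove_hint, zrange=(-30.0, 30.0))
        line0, _ = distal_humeral_axis(bone, lm)
        Q, t = random_rigid_transform(rng)
        mesh2 = bone.mesh.copy()
        mesh2.vertices = mesh2.vertices @ Q.T + t
        lm2 = LandmarkSet(lm.medial_picks @ Q.T + t, lm.lateral_picks @ Q.T + t,
                          lm.groove_points @ Q.T + t, lm.shaft_zrange)
        line2, _ = distal_humeral_axis(BoneMesh(mesh2, "shaft-rt", "right"), lm2)
        assert geo.angle_deg(line2.direction, Q @ line0.direction) < 1e-6

    def test_bowed_shaft_recovered_within_a_degree(self):
        spec = SyntheticSpec(shaft_bow_deg=2.0, landmark_jitter_mm=0.0, seed=3)
        bone, lm, gt = generate_specimen(spec)
        line, _ = distal_humeral_axis(bone, lm)
        assert geo.angle_deg(line.direction, gt.long_axis.direction) < 1.0

    def test_short_window_rejected(self):
        bone = self._cylinder_bone()
        lm = landmarks_with(zrange=(0.0, 10.0))
        with pytest.raises(LandmarkError):
            distal_humeral_axis(bone, lm)


class TestTrueFeAxis:
    def test_exact_groove_points_recover_axis(self):
        truth_n = np.array([1.0, 0.05, 0.1])
        truth_n /= np.linalg.norm(truth_n)
        lm = landmarks_with(groove=circle_points((2, -1, 3), 9.0, truth_n))
        line, circle = true_fe_axis(lm, lateral_to_medial=(1, 0, 0))
        assert circle.converged
        assert geo.angle_deg(line.direction, truth_n) < 1e-7
        assert np.linalg.norm(circle.center - (2, -1, 3)) < 1e-8
        assert abs(circle.radius - 9.0) < 1e-8

    def test_jittered_groove_points_recover_axis_tightly(self):
        rng = np.random.default_rng(42)
        truth_n = np.array([0.98, 0.1, 0.17])
        truth_n /= np.linalg.norm(truth_n)
        pts = circle_points((0, 5, -2), 9.0, truth_n, n=20, rng=rng, sigma=0.3)
        lm = landmarks_with(groove=pts)
        line, circle = true_fe_axis(lm, lateral_to_medial=truth_n)
        assert geo.angle_deg(line.direction, truth_n) < 1.5
        assert np.linalg.norm(circle.center - (0, 5, -2)) < 0.5

    def test_quarter_arc_still_converges(self):
        rng = np.random.default_rng(1)
        pts = circle_points((0, 0, 0), 9.0, (1, 0, 0), n=20, arc_deg=90.0,
                            rng=rng, sigma=0.1)
        line, circle = true_fe_axis(landmarks_with(groove=pts),
                                    lateral_to_medial=(1, 0, 0))
        assert circle.converged
        # partial-arc fits are less stable but must stay bounded
        assert geo.angle_deg(line.direction, (1, 0, 0)) < 10.0

    def test_fe_direction_equals_circle_normal_and_is_oriented(self):
        lm = landmarks_with(groove=circle_points((0, 0, 0), 9.0, (-1, 0, 0)))
        line, circle = true_fe_axis(lm, lateral_to_medial=(1, 0, 0))
        assert np.allclose(line.direction, circle.normal)
        assert line.direction @ np.array([1.0, 0, 0]) > 0


class TestGroundTruthSolver:
    def test_zero_translations_with_rotations_unrealizable(self):
        from elbowaxis.errors import GenerationError
        spec = SyntheticSpec(varus_deg=2.0, external_deg=1.0,
                             medial_offset_mm=(0, 0, 0), lateral_offset_mm=(0, 0, 0))
        with pytest.raises(GenerationError):
            solve_ground_truth(spec)

    def test_alpha_beta_land_in_plausible_band(self):
        gt = solve_ground_truth(SyntheticSpec())
        assert 70.0 < gt.alpha_deg < 110.0
        assert 70.0 < gt.beta_deg < 110.0
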