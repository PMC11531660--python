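"""Unit and property tests for the 3D fitting primitives."""

import numpy as np
import pytest
import trimesh

from elbowaxis import geometry as geo
from elbowaxis.errors import (DegenerateInputError, DegenerateProjectionError,
                              EmptyIntersectionError)
from elbowaxis.geometry import Line3, Plane3

from .oracles import (grid_circle_objective, grid_ellipse_objective,
                      random_rigid_transform, spectral_line_direction)


def circle_points(center, radius, normal, n=20, arc_deg=360.0, rng=None, sigma=0.0):
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    u, v = geo.orthonormal_basis(normal)
    t = np.radians(np.linspace(0.0, arc_deg, n, endpoint=False))
    pts = center + radius * (np.outer(np.cos(t), u) + np.outer(np.sin(t), v))
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, pts.shape)
    return pts


class TestFitLineTLS:
    def test_collinear_points_recover_the_line(self):
        line = geo.fit_line_tls([(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        assert np.allclose(line.anchor, (0, 0, 1))
        assert np.allclose(line.direction, (0, 0, 1))

    def test_two_points_direction_sign_convention(self):
        line = geo.fit_line_tls([(1, 0, 0), (3, 0, 0)], orient_along=(1, 0, 0))
        assert np.allclose(line.direction, (1, 0, 0))
        assert line.distance_to_point((2, 0, 0)) < 1e-12

    def test_matches_spectral_oracle_on_jittered_points(self, rng):
        base = np.array([1.0, 2.0, 0.5]) + np.outer(np.linspace(-3, 3, 5),
                                                    [0.2, 0.3, 0.93])
        pts = base + rng.normal(0.0, 0.1, base.shape)
        line = geo.fit_line_tls(pts)
        oracle = spectral_line_direction(pts)
        assert min(np.linalg.norm(line.direction - oracle),
                   np.linalg.norm(line.direction + oracle)) < 1e-9

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateInputError):
            geo.fit_line_tls([(1, 1, 1)] * 4)


class TestFitEllipsePlanar:
    plane = Plane3((0, 0, 3), (0, 0, 1))

    def _samples(self, a, b, center, n=36):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([center[0] + a * np.cos(t),
                                center[1] + b * np.sin(t),
                                np.full(n, center[2])])

    def test_exact_samples_recover_ellipse(self):
        pts = self._samples(12.0, 8.0, (1.0, 2.0, 3.0))
        e = geo.fit_ellipse_planar(pts, self.plane)
        assert np.allclose(e.center, (1, 2, 3), atol=1e-8)
        assert abs(e.a - 12) < 1e-8 and abs(e.b - 8) < 1e-8
        assert e.rms_residual < 1e-8

    def test_circle_special_case(self):
        pts = self._samples(10.0, 10.0, (0.0, 0.0, 3.0))
        e = geo.fit_ellipse_planar(pts, self.plane)
        assert abs(e.a - 10) < 1e-8 and abs(e.b - 10) < 1e-8
        assert np.allclose(e.center, (0, 0, 3), atol=1e-8)

    def test_noisy_fit_beats_grid_oracle(self, rng):
        pts = self._samples(12.0, 8.0, (0.5, -0.3, 3.0))
        pts[:, :2] += rng.normal(0.0, 0.3, (len(pts), 2))
        e = geo.fit_ellipse_planar(pts, self.plane, fit_orientation=False)
        u0, v0 = geo.orthonormal_basis(self.plane.normal)
        xy = np.column_stack([(pts - self.plane.anchor) @ u0,
                              (pts - self.plane.anchor) @ v0])
        # axis-aligned objective of the returned fit
        c2 = np.array([(e.center - self.plane.anchor) @ u0,
                       (e.center - self.plane.anchor) @ v0])
        from .oracles import ellipse_objective_2d
        # the in-plane basis may swap a/b relative to the sample axes
        fit_obj = min(ellipse_objective_2d(xy, c2[0], c2[1], e.a, e.b),
                      ellipse_objective_2d(xy, c2[0], c2[1], e.b, e.a))
        oracle = grid_ellipse_objective(xy)
        assert fit_obj <= oracle * (1.0 + 1e-6)

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(ValueError):
            geo.fit_ellipse_planar(self._samples(12, 8, (0, 0, 3))[:4], self.plane)
        collinear = np.column_stack([np.linspace(0, 5, 8), np.zeros(8), np.full(8, 3.0)])
        with pytest.raises(DegenerateInputError):
            geo.fit_ellipse_planar(collinear, self.plane)

    def test_off_plane_points_rejected(self):
        pts = self._samples(12.0, 8.0, (0.0, 0.0, 2.0))  # on z=2, plane is z=3
        with pytest.raises(ValueError):
            geo.fit_ellipse_planar(pts, self.plane)


class TestFitCircle3D:
    def test_exact_points_recover_circle(self):
        pts = circle_points((0, 0, 0), 12.0, (0, 0, 1))
        c = geo.fit_circle_3d(pts, orient_reference=(0, 0, 1))
        assert c.converged
        assert np.allclose(c.center, 0, atol=1e-8)
        assert abs(c.radius - 12) < 1e-8
        assert np.max(np.abs(c.radial_residuals)) < 1e-8
        assert np.max(np.abs(c.out_of_plane_residuals)) < 1e-8

    def test_flipped_init_normal_is_reoriented(self):
        pts = circle_points((0, 0, 0), 12.0, (0, 0, 1))
        init = geo.Circle3D(center=(0.1, -0.1, 0.05), radius=11.0, normal=(0, 0, -1))
        c = geo.fit_circle_3d(pts, init=init, orient_reference=(0, 0, 1))
        assert c.normal @ np.array([0, 0, 1]) > 0.999999
        assert abs(c.radius - 12) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_fit_beats_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = circle_points((1, -2, 0.5), 12.0, (0.2, 0.1, 0.97), rng=rng, sigma=0.3)
        c = geo.fit_circle_3d(pts)
        assert c.converged
        oracle = grid_circle_objective(pts)
        assert c.objective <= oracle * (1.0 + 1e-6)

    def test_collinear_and_too_few_points_raise(self):
        with pytest.raises(DegenerateInputError):
            geo.fit_circle_3d(np.outer(np.arange(6), [1.0, 0.5, 0.2]))
        with pytest.raises(ValueError):
            geo.fit_circle_3d(circle_points((0, 0, 0), 5, (0, 0, 1))[:3])

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_rigid_transform_invariance_of_fitted_radius(self, seed):
        rng = np.random.default_rng(seed)
        pts = circle_points((0, 1, 2), 10.0, (0.1, 0.9, 0.4), rng=rng, sigma=0.4)
        c0 = geo.fit_circle_3d(pts)
        Q, t = random_rigid_transform(rng)
        c1 = geo.fit_circle_3d(pts @ Q.T + t)
        assert abs(c0.radius - c1.radius) < 1e-7
        assert np.max(np.abs(np.sort(c0.radial_residuals)
                             - np.sort(c1.radial_residuals))) < 1e-7


class TestDirectionOps:
    def test_projection_examples(self):
        plane = Plane3((0, 0, 0), (0, 0, 1))
        p = geo.project_direction(np.array([1, 0, 1]) / np.sqrt(2), plane)
        assert np.allclose(p, (1, 0, 0), atol=1e-12)
        d = np.array([0.6, 0.8, 0.0])
        assert np.allclose(geo.project_direction(d, plane), d, atol=1e-12)

    def test_projection_idempotent_and_orthogonal(self, rng):
        for _ in range(50):
            d = rng.normal(size=3)
            n = rng.normal(size=3)
            if abs(np.dot(d / np.linalg.norm(d), n / np.linalg.norm(n))) > 0.99:
                continue
            plane = Plane3((0, 0, 0), n)
            p1 = geo.project_direction(d, plane)
            p2 = geo.project_direction(p1, plane)
            assert abs(p1 @ plane.normal) < 1e-12
            assert np.linalg.norm(p1 - p2) < 1e-12

    def test_projection_of_parallel_direction_raises(self):
        plane = Plane3((0, 0, 0), (0, 0, 1))
        with pytest.raises(DegenerateProjectionError):
            geo.project_direction((0, 0, 1), plane)

    def test_angle_examples_and_constructed_rotation(self):
        assert geo.angle_deg((1, 0, 0), (1, 0, 0)) == 0.0
        assert abs(geo.angle_deg((1, 0, 0), (0, 1, 0)) - 90.0) < 1e-12
        th = np.radians(2.2)
        d2 = np.array([np.cos(th), np.sin(th), 0.0])
        assert abs(geo.angle_deg((1, 0, 0), d2) - 2.2) < 1e-9

    def test_angle_invariant_under_rotation(self, rng):
        d1, d2 = rng.normal(size=3), rng.normal(size=3)
        Q, _ = random_rigid_transform(rng)
        a0 = geo.angle_deg(d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2))
        a1 = geo.angle_deg(Q @ d1 / np.linalg.norm(d1), Q @ d2 / np.linalg.norm(d2))
        assert abs(a0 - a1) < 1e-9


class TestMeshProbes:
    def test_cylinder_section_perimeter(self):
        mesh = trimesh.creation.cylinder(radius=1.0, height=4.0, sections=128)
        contours = geo.plane_mesh_section(mesh, Plane3((0, 0, 0.3), (0, 0, 1)))
        primary = [c for c in contours if c.primary]
        assert len(primary) == 1
        assert abs(primary[0].perimeter - 2 * np.pi) < 0.01

    def test_section_outside_mesh_raises(self):
        mesh = trimesh.creation.cylinder(radius=1.0, height=4.0)
        with pytest.raises(EmptyIntersectionError):
            geo.plane_mesh_section(mesh, Plane3((0, 0, 10.0), (0, 0, 1)))

    def test_line_through_sphere_center_symmetric(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        hits = geo.line_mesh_intersections(Line3((0, 0, 0), (1, 0, 0)), mesh)
        assert len(hits) == 2
        ks = [k for _, k in hits]
        assert abs(ks[0] + ks[1]) < 1e-6
        assert abs(abs(ks[0]) - 2.0) < 0.01

    def test_tangent_and_missing_lines_do_not_crash(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        hits = geo.line_mesh_intersections(Line3((0, 0, 1.0), (1, 0, 0)), mesh)
        assert len(hits) <= 2
        assert geo.line_mesh_intersections(Line3((0, 0, 5.0), (1, 0, 0)), mesh) == []
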