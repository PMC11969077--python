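"""Room-frame conventions, projection, and the least-squares isocenter solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from wliso.geometry import (
    MachineGeometry,
    PlaneCoord,
    Ray,
    bcr_from_field_center,
    beam_direction,
    imager_axes,
    project_to_isoplane,
    solve_bb_position,
    solve_isocenter,
    source_position,
    wrap_angle,
)

GEOM = MachineGeometry()


def _rot2(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


class TestConventions:
    @pytest.mark.parametrize(
        "gantry, expected",
        [(0, (0, -1000, 0)), (180, (0, 1000, 0)), (90, (1000, 0, 0))],
    )
    def test_source_position_anchors(self, gantry, expected):
        np.testing.assert_allclose(
            source_position(gantry, GEOM), expected, atol=1e-9
        )

    @pytest.mark.parametrize("gantry, expected", [(0, (0, 1, 0)), (90, (-1, 0, 0))])
    def test_beam_direction(self, gantry, expected):
        np.testing.assert_allclose(beam_direction(gantry), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "gantry, u, v",
        [
            (0, (1, 0, 0), (0, 0, 1)),
            (90, (0, 1, 0), (0, 0, 1)),
            (45, (np.sqrt(2) / 2, np.sqrt(2) / 2, 0), (0, 0, 1)),
        ],
    )
    def test_imager_axes(self, gantry, u, v):
        u_hat, v_hat = imager_axes(gantry)
        np.testing.assert_allclose(u_hat, u, atol=1e-12)
        np.testing.assert_allclose(v_hat, v, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-720, 720, allow_nan=False))
    def test_triad_orthonormal_any_gantry(self, gantry):
        u_hat, v_hat = imager_axes(gantry)
        b = beam_direction(gantry)
        basis = np.stack([u_hat, v_hat, b])
        np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-12)
        # beam points from source toward the origin
        assert beam_direction(gantry) @ source_position(gantry, GEOM) == pytest.approx(
            -GEOM.sad_mm
        )

    def test_wrap_angle(self):
        assert wrap_angle(-90) == 270
        assert wrap_angle(360) == 0


class TestProjection:
    def test_origin_projects_to_center(self):
        assert project_to_isoplane(np.zeros(3), 33.0, GEOM) == PlaneCoord(0, 0)

    def test_point_in_iso_plane_unmagnified(self):
        pc = project_to_isoplane(np.array([1.0, 0, 0]), 0, GEOM)
        assert pc.u == pytest.approx(1.0, abs=1e-12)

    def test_similar_triangles_downstream_point(self):
        # 10 mm downstream of the iso plane: scaled by 1000/1010
        pc = project_to_isoplane(np.array([1.0, 10.0, 0]), 0, GEOM)
        assert pc.u == pytest.approx(1000 / 1010, abs=1e-9)
        assert pc.v == pytest.approx(0, abs=1e-12)

    def test_point_behind_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            project_to_isoplane(np.array([0, -1500.0, 0]), 0, GEOM)

    @pytest.mark.parametrize(
        "fc, gantry, origin, direction",
        [
            (PlaneCoord(0, 0), 0, (0, 0, 0), (0, 1, 0)),
            (PlaneCoord(0.5, 0), 0, (0.5, 0, 0), (0, 1, 0)),
            (PlaneCoord(0.5, 0), 90, (0, 0.5, 0), (-1, 0, 0)),
        ],
    )
    def test_bcr_construction(self, fc, gantry, origin, direction):
        ray = bcr_from_field_center(fc, gantry, GEOM)
        np.testing.assert_allclose(ray.origin, origin, atol=1e-12)
        np.testing.assert_allclose(ray.direction, direction, atol=1e-12)


class TestSolveIsocenter:
    def test_requires_two_rays(self):
        with pytest.raises(ValueError, match="at least 2"):
            solve_isocenter([Ray(np.zeros(3), np.array([0, 1.0, 0]))])

    def test_exact_intersection_recovered(self, rng):
        q = np.array([0.3, -0.2, 0.1])
        rays = []
        for g in (10, 75, 200, 290):
            d = beam_direction(g)
            rays.append(Ray(origin=q - 5 * d, direction=d))
        sol = solve_isocenter(rays)
        np.testing.assert_allclose(sol.position, q, atol=1e-10)
        assert sol.rms_mm == pytest.approx(0, abs=1e-10)
        assert not sol.condition_flag

    def test_symmetric_coplanar_offsets(self):
        # four cardinal-gantry rays each shifted 0.2 mm along +u: by
        # symmetry the solution stays at the origin with all distances 0.2
        rays = [
            bcr_from_field_center(PlaneCoord(0.2, 0), g, GEOM)
            for g in (0, 90, 180, 270)
        ]
        sol = solve_isocenter(rays)
        np.testing.assert_allclose(sol.position, np.zeros(3), atol=1e-12)
        np.testing.assert_allclose(sol.per_ray_distance_mm, 0.2, atol=1e-12)
        assert sol.rms_mm == pytest.approx(
            np.sqrt(np.mean(sol.per_ray_distance_mm**2)), abs=1e-9
        )

    def test_agrees_with_derivative_free_minimizer(self, rng):
        rays = [
            bcr_from_field_center(
                PlaneCoord(*rng.uniform(-0.5, 0.5, 2)), rng.uniform(0, 360)
            )
            for _ in range(20)
        ]
        sol = solve_isocenter(rays)

        def objective(x):
            return float(sum(r.distance_to(x) ** 2 for r in rays))

        m = minimize(
            objective, x0=np.zeros(3), method="Powell",
            options=dict(xtol=1e-14, ftol=1e-16, maxiter=100000),
        )
        assert np.linalg.norm(sol.position - m.x) < 1e-8

    def test_parallel_rays_flagged_not_fatal(self):
        d = np.array([0, 1.0, 0])
        rays = [Ray(np.array([x, 0, 0.0]), d) for x in (-1.0, 1.0)]
        sol = solve_isocenter(rays)
        assert sol.condition_flag
        # minimum-norm solution sits midway, at y = 0
        np.testing.assert_allclose(sol.position, [0, 0, 0], atol=1e-9)

    def test_invariant_to_permutation_and_uniform_duplication(self, rng):
        rays = [
            bcr_from_field_center(
                PlaneCoord(*rng.uniform(-1, 1, 2)), rng.uniform(0, 360)
            )
            for _ in range(8)
        ]
        base = solve_isocenter(rays).position
        perm = solve_isocenter(rays[::-1]).position
        doubled = solve_isocenter(rays + rays).position
        np.testing.assert_allclose(perm, base, atol=1e-12)
        np.testing.assert_allclose(doubled, base, atol=1e-12)

    def test_gantry_opposition_cancels_constant_u_offset(self):
        # a fixed +u field offset at opposed gantry pairs cancels in x, y
        rays = [
            bcr_from_field_center(PlaneCoord(0.4, 0), g, GEOM)
            for g in (0, 90, 180, 270, 45, 225)
        ]
        sol = solve_isocenter(rays)
        assert abs(sol.position[0]) < 1e-9
        assert abs(sol.position[1]) < 1e-9

    def test_opposing_collimator_offset_cancels_exactly(self):
        # constant collimator-frame offset c contributes R(C) c to the
        # field center; solving over {C, C+180} pairs equals the
        # zero-offset isocenter to machine precision
        c = np.array([0.37, -0.21])
        gantries = (225, 270, 315, 0, 45, 90, 135, 180)
        for coll in (0, 45, 90):
            rays = []
            for g in gantries:
                for cc in (coll, coll + 180):
                    fc = _rot2(cc) @ c
                    rays.append(bcr_from_field_center(PlaneCoord(*fc), g, GEOM))
            ref = [
                bcr_from_field_center(PlaneCoord(0, 0), g, GEOM)
                for g in gantries for _ in range(2)
            ]
            delta = solve_isocenter(rays).position - solve_isocenter(ref).position
            assert np.linalg.norm(delta) < 1e-9


class TestSolveBBPosition:
    def _projections(self, bb, gantries):
        return [(project_to_isoplane(bb, g, GEOM), g) for g in gantries]

    def test_bb_at_origin(self):
        sol = solve_bb_position(
            self._projections(np.zeros(3), (0, 90, 180)), GEOM
        )
        np.testing.assert_allclose(sol.position, np.zeros(3), atol=1e-12)

    def test_noiseless_recovery_cardinal_angles(self):
        bb = np.array([1.0, -0.5, 0.7])
        sol = solve_bb_position(
            self._projections(bb, (0, 90, 180, 270)), GEOM, mode="parallel"
        )
        # parallax error is second order and cancels between opposed
        # gantry angles: recovery far below a micron
        assert np.linalg.norm(sol.position - bb) < 1e-6

    def test_perspective_mode_exact(self):
        bb = np.array([1.7, 0.4, -1.2])
        sol = solve_bb_position(
            self._projections(bb, (30, 120, 260)), GEOM, mode="perspective"
        )
        assert np.linalg.norm(sol.position - bb) < 1e-9

    def test_parallel_vs_perspective_bounded(self):
        bb = np.array([2.0, 0, 0])
        proj = self._projections(bb, (0, 45, 90, 180, 270))
        par = solve_bb_position(proj, GEOM, mode="parallel").position
        per = solve_bb_position(proj, GEOM, mode="perspective").position
        assert np.linalg.norm(par - per) < 0.01

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            solve_bb_position(self._projections(np.zeros(3), (0, 90)), GEOM, mode="x")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        st.integers(0, 10_000),
    )
    def test_round_trip_recovery_property(self, point, angle_seed):
        # any |p| <= 5 mm point is recovered from >= 3 noiseless
        # projections within 0.01 mm
        bb = np.array(point)
        rng = np.random.default_rng(angle_seed)
        gantries = rng.uniform(0, 360, size=4)
        if np.ptp(np.sort(gantries % 180)) < 5:  # nearly collinear beams
            gantries = np.array([0, 60, 120, 250.0])
        sol = solve_bb_position(
            self._projections(bb, gantries), GEOM, mode="perspective"
        )
        assert np.linalg.norm(sol.position - bb) < 0.01
        # the parallel-ray approximation degrades gracefully: first order
        # in |p| zeta / SAD, well under 0.05 mm anywhere in the +/-5 mm cube
        par = solve_bb_position(self._projections(bb, gantries), GEOM)
        assert np.linalg.norm(par.position - bb) < 0.05


class TestMachineGeometry:
    def test_iso_plane_pitch(self):
        assert GEOM.pixel_pitch_iso_mm == pytest.approx(0.224)

    @pytest.mark.parametrize(
        "kwargs", [dict(sad_mm=-1), dict(sid_mm=900), dict(pixel_pitch_imager_mm=0)]
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MachineGeometry(**kwargs)
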