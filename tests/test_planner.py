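"""Virtual osteotomy, reorientation solve and fiducial handling."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from raoplan.errors import PlanningError
from raoplan.geometry import RigidTransform, Sphere, build_frame, fit_sphere
from raoplan.measure import measure_asa, rim_crossings
from raoplan.phantom import DEFAULT_COVERAGE, PhantomParams, make_hip_phantom
from raoplan.planner import (PlanTargets, place_fiducials, plan_case,
                             relocate_fiducials, spherical_osteotomy)


class TestSphericalOsteotomy:
    def test_fragment_contains_rim_remainder_does_not(self, phantom, plan):
        rim = phantom.landmarks.rim_polyline
        d_frag = cKDTree(plan.fragment_mesh.vertices).query(rim)[0]
        d_rem = cKDTree(plan.remainder_mesh.vertices).query(rim)[0]
        assert d_frag.max() < 2.0      # rim lies on the fragment surface
        assert d_rem.min() > 10.0      # and nowhere near the remainder

    def test_fragment_inside_sphere(self, plan):
        r = np.linalg.norm(plan.fragment_mesh.vertices
                           - plan.osteotomy_sphere.center, axis=1)
        assert r.max() <= plan.osteotomy_sphere.radius + 1e-6

    def test_area_partition(self, phantom, plan):
        total = phantom.pelvis_mesh.area
        split = plan.fragment_mesh.area + plan.remainder_mesh.area
        assert split == pytest.approx(total, rel=0.01)

    def test_proximal_clearance_matches_construction(self):
        # a phantom cut with a sphere 25 mm larger than the cup radius leaves
        # a ~25 mm osteotomy margin above the rim apex
        params = PhantomParams()
        model = make_hip_phantom(params)
        radius = params.cup_radius + 25.0
        frag, _ = spherical_osteotomy(model, Sphere(np.zeros(3), radius))
        apex = model.landmarks.rim_polyline[
            np.argmax(model.landmarks.rim_polyline[:, 2])]
        r = np.linalg.norm(frag.vertices, axis=1)
        cut_edge = frag.vertices[np.abs(r - radius) < 0.5]
        clearance = np.linalg.norm(cut_edge - apex, axis=1).min()
        assert clearance == pytest.approx(25.0, abs=1.5)

    def test_rim_outside_sphere_rejected(self, phantom):
        # a sphere shifted inferiorly leaves the superior rim outside the cut
        with pytest.raises(PlanningError):
            spherical_osteotomy(phantom, Sphere(np.array([0.0, 0.0, -8.0]), 30.05))

    def test_far_center_rejected(self, phantom):
        with pytest.raises(PlanningError):
            spherical_osteotomy(phantom, Sphere(np.array([20.0, 0, 0]), 42.5))

    def test_enclosing_sphere_rejected(self):
        small = make_hip_phantom(PhantomParams(collar_radius_mm=41.0,
                                               wing_length_mm=0.0,
                                               wing_twist_deg=0.0))
        with pytest.raises(PlanningError):
            spherical_osteotomy(small, Sphere(np.zeros(3), 59.0))


class TestSolveReorientation:
    def test_default_phantom_reaches_targets(self, plan):
        # the planning goals: flat roof, anterior CE 45-50, head centre
        # 35-40 mm from the Koehler proxy
        assert plan.achieved["aro_deg"] == pytest.approx(0.0, abs=0.5)
        assert 45.0 <= plan.achieved["anterior_ce_deg"] <= 50.0
        assert 35.0 <= plan.achieved["koehler_mm"] <= 40.0
        assert plan.achieved["rotation_deg"] <= 60.0

    def test_phantom_already_at_targets_yields_near_identity(self):
        coverage = {"12:00": 150.0, "13:30": 142.0, "15:00": 137.5,
                    "16:30": 140.0, "18:00": 145.0, "19:30": 140.0,
                    "21:00": 137.5, "22:30": 142.0}
        params = PhantomParams(coverage_by_clock=coverage,
                               koehler_offset_mm=37.5)
        model = make_hip_phantom(params)
        p = plan_case(model, with_fiducials=False)
        assert p.reorientation.rotation_angle_deg() < 1.5
        assert np.linalg.norm(p.reorientation.translation) < 1.0

    def test_lateral_rotation_monotonically_increases_asa12(self, phantom,
                                                            frame):
        # bisection validity: rotating the fragment laterally about the
        # anteroposterior axis strictly raises the 12:00 sector angle
        rim = phantom.landmarks.rim_polyline
        values = []
        for beta in range(0, 12, 2):
            T = RigidTransform.from_rotvec(-beta * frame.y_axis,
                                           center=np.zeros(3))
            pts = rim_crossings(T.apply(rim), np.zeros(3), frame, 0.0)
            p = max(pts, key=np.linalg.norm)
            values.append(np.degrees(np.arctan2(p @ frame.z_axis,
                                                p @ frame.x_axis)))
        assert np.all(np.diff(values) > 0)


class TestFiducials:
    def test_four_points_evenly_spaced_on_superolateral_arc(self, phantom,
                                                            plan, frame):
        fid = plan.fiducials
        assert fid.pre_points.shape == (4, 3)
        local = frame.to_local(fid.pre_points)
        az = np.degrees(np.arctan2(local[:, 1], local[:, 2]))
        assert np.allclose(az, [-30, -10, 10, 30], atol=2.0)
        assert np.allclose(np.diff(az), 20.0, atol=2.0)
        # offset ~5 mm peripheral to the rim
        r = np.linalg.norm(fid.pre_points, axis=1)
        assert np.all((r > 28.0) & (r < 34.0))

    def test_points_lie_on_fragment_surface(self, plan):
        from raoplan.geometry import closest_point_on_mesh
        _, d = closest_point_on_mesh(plan.fragment_mesh, plan.fiducials.pre_points)
        assert d.max() < 0.2

    def test_relocation_is_exact_and_isometric(self, plan):
        fid = plan.fiducials
        T = plan.reorientation
        assert np.allclose(fid.relocated_points, T.apply(fid.pre_points),
                           atol=1e-12)
        d_pre = np.linalg.norm(fid.pre_points[:, None] - fid.pre_points[None], axis=2)
        d_rel = np.linalg.norm(fid.relocated_points[:, None]
                               - fid.relocated_points[None], axis=2)
        assert np.allclose(d_pre, d_rel, atol=1e-9)

    def test_label_pairing(self, plan):
        assert plan.fiducials.pairs() == {"#1": "#5", "#2": "#6",
                                          "#3": "#7", "#4": "#8"}

    def test_identity_relocation(self, plan):
        fid = relocate_fiducials(plan.fiducials, RigidTransform.identity())
        assert np.allclose(fid.relocated_points, fid.pre_points, atol=1e-12)

    def test_narrow_arc_rejected(self, phantom, plan, frame):
        with pytest.raises(PlanningError):
            place_fiducials(plan.fragment_mesh, phantom.landmarks.rim_polyline,
                            frame, arc_span_deg=3.0)

    def test_n_other_than_four_rejected(self, phantom, plan, frame):
        with pytest.raises(PlanningError):
            place_fiducials(plan.fragment_mesh, phantom.landmarks.rim_polyline,
                            frame, n=3)
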