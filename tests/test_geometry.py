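"""Geometric primitives: sphere fit, Kabsch, ICP, frames, sections."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from raoplan.errors import DegenerateInputError
from raoplan.geometry import (RigidTransform, Sphere, build_frame,
                              centroid_align, closest_point_on_mesh,
                              fit_sphere, icp, kabsch, plane_section,
                              robust_icp)


def random_transform(rng, rot=30.0, trans=30.0):
    return RigidTransform.random(rng, rot, trans)


def sphere_points(rng, center, radius, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return center + radius * v


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

class TestRigidTransform:
    def test_group_laws(self, rng):
        for _ in range(50):
            T = random_transform(rng)
            U = random_transform(rng)
            V = random_transform(rng)
            ident = T @ T.inverse()
            assert np.abs(ident.rotation - np.eye(3)).max() < 1e-9
            assert np.abs(ident.translation).max() < 1e-9
            p = rng.normal(size=(5, 3)) * 40
            lhs = ((T @ U) @ V).apply(p)
            rhs = (T @ (U @ V)).apply(p)
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rotation_about_center_fixes_center(self):
        c = np.array([3.0, -2.0, 7.0])
        T = RigidTransform.from_rotvec([0, 25.0, 0], center=c)
        assert np.allclose(T.apply(c), c, atol=1e-12)
        assert T.rotation_angle_deg() == pytest.approx(25.0, abs=1e-9)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

class TestFitSphere:
    def test_exact_recovery(self, rng):
        c = np.array([10.0, -5.0, 3.0])
        fit = fit_sphere(sphere_points(rng, c, 24.0, 100))
        assert np.linalg.norm(fit.center - c) < 1e-9
        assert fit.radius == pytest.approx(24.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_center_accuracy_monte_carlo(self, rng):
        # 200 replicates of 500 points with 0.3 mm radial noise: the centre
        # estimate stays well inside 0.1 mm
        c = np.array([2.0, 1.0, -4.0])
        errs = []
        for _ in range(200):
            pts = sphere_points(rng, c, 24.0, 500)
            pts += rng.normal(0.0, 0.3, size=pts.shape)
            errs.append(np.linalg.norm(fit_sphere(pts).center - c))
        assert np.mean(errs) < 0.1
        assert np.quantile(errs, 0.95) < 0.1

    @pytest.mark.parametrize("bad", [
        np.zeros((3, 3)),                                   # too few
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]),  # coplanar
    ])
    def test_degenerate_inputs(self, bad):
        with pytest.raises(DegenerateInputError):
            fit_sphere(bad)


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_exact_recovery(self, rng):
        src = rng.normal(size=(10, 3)) * 30
        T = random_transform(rng)
        est, resid = kabsch(src, T.apply(src))
        assert (est.inverse() @ T).rotation_angle_deg() < 1e-9
        assert resid.max() < 1e-9

    def test_collinear_points_rejected(self):
        src = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            kabsch(src, src + 1.0)

    def test_clustered_fiducials_give_larger_rotation_error(self, rng):
        # fiducial spread matters: 4 markers on a 15-degree rim arc localize
        # rotation far worse than 4 markers spread over 180 degrees
        def arc_points(span_deg):
            ang = np.radians(np.linspace(-span_deg / 2, span_deg / 2, 4))
            return np.column_stack([np.zeros(4) - 5.0,
                                    26 * np.sin(ang), 26 * np.cos(ang)])

        errors = {15.0: [], 180.0: []}
        for span, out in errors.items():
            pts = arc_points(span)
            for _ in range(500):
                T = random_transform(rng, rot=10.0, trans=5.0)
                noisy = T.apply(pts) + rng.normal(0, 0.5, size=pts.shape)
                est, _ = kabsch(pts, noisy)
                out.append((est.inverse() @ T).rotation_angle_deg())
        assert np.mean(errors[15.0]) > np.mean(errors[180.0])


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

class TestICP:
    def test_identical_inputs_converge_immediately(self, rng):
        pts = rng.normal(size=(300, 3)) * 20
        res = icp(pts, pts, init=RigidTransform.identity())
        assert res.final_mse == 0.0
        assert res.iterations == 0
        assert res.converged_by == "mse_tol"

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            icp(np.empty((0, 3)), np.ones((5, 3)))

    def test_single_iteration_matches_bruteforce_oracle(self, rng):
        # on a small mesh, one ICP update must equal Kabsch on exhaustive
        # nearest-neighbour pairs computed by brute force
        blob = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
        src = blob.vertices * np.array([1.0, 1.3, 1.7])  # 42 vertices
        T = random_transform(rng, rot=10.0, trans=5.0)
        dst = T.apply(src) + rng.normal(0, 0.5, size=src.shape)
        init = centroid_align(src, dst)
        res = icp(src, dst, init=init, max_iter=1, mse_tol=1e-30)
        moved = init.apply(src)
        d2 = ((moved[:, None, :] - dst[None, :, :]) ** 2).sum(axis=2)
        nn = np.argmin(d2, axis=1)
        expected, _ = kabsch(src, dst[nn])
        assert (res.transform.inverse() @ expected).rotation_angle_deg() < 1e-9

    def test_registration_self_consistency(self, planning_model, rng):
        # a rigidly moved copy of the planning pelvis is recovered to the
        # stated convergence level from centroid initialisation
        src = planning_model.pelvis_mesh.vertices
        for _ in range(5):
            T = random_transform(rng, rot=30.0, trans=30.0)
            dst_mesh = T.transform_mesh(planning_model.pelvis_mesh)
            res = robust_icp(src, dst_mesh,
                             init=centroid_align(src, dst_mesh.vertices))
            assert res.final_mse <= 1e-5
            assert (res.transform.inverse() @ T).rotation_angle_deg() < 0.1


def test_closest_point_on_mesh_matches_bruteforce(rng):
    mesh = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    pts = rng.normal(size=(40, 3)) * 12
    _, dist = closest_point_on_mesh(mesh, pts)
    tri = mesh.triangles
    brute = np.empty(len(pts))
    for i, p in enumerate(pts):
        near = trimesh.triangles.closest_point(tri, np.repeat([p], len(tri), axis=0))
        brute[i] = np.linalg.norm(near - p, axis=1).min()
    assert np.allclose(dist, brute, atol=1e-9)


# ---------------------------------------------------------------------------
# anatomical frame
# ---------------------------------------------------------------------------

class TestBuildFrame:
    def test_phantom_frame_is_canonical(self, phantom):
        f = build_frame(phantom.landmarks, phantom.side)
        assert np.allclose(f.origin, [0, 0, 0], atol=1e-12)
        assert np.allclose(f.x_axis, [1, 0, 0], atol=1e-12)
        assert np.allclose(f.y_axis, [0, 1, 0], atol=1e-12)
        assert np.allclose(f.z_axis, [0, 0, 1], atol=1e-12)

    def test_equivariance_under_rigid_motion(self, phantom, rng):
        f0 = build_frame(phantom.landmarks, phantom.side)
        for _ in range(20):
            T = random_transform(rng)
            f1 = build_frame(phantom.landmarks.transformed(T), phantom.side)
            assert np.allclose(f1.origin, T.apply(f0.origin), atol=1e-9)
            for ax in ("x_axis", "y_axis", "z_axis"):
                assert np.allclose(getattr(f1, ax),
                                   T.rotation @ getattr(f0, ax), atol=1e-9)

    def test_coincident_asis_rejected(self, phantom):
        # degenerate APP geometry is caught at landmark construction already
        with pytest.raises(DegenerateInputError):
            phantom.landmarks.replace(ASIS_left=phantom.landmarks.ASIS_right)


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------

class TestPlaneSection:
    def test_sphere_equator_radius(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        polys = plane_section(mesh, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert polys
        pts = np.vstack(polys)
        assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 1.0, atol=5e-3)

    def test_plane_outside_bounding_box(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        assert plane_section(mesh, np.array([0, 0, 5.0]),
                             np.array([0, 0, 1.0])) == []

    def test_cup_section_arc_length_matches_closed_form(self, phantom, frame):
        # mid-frontal (12:00) section of the articular cup: superior arc
        # length equals cup_radius * (rim polar - fossa polar)
        from raoplan.phantom import PhantomParams, coverage_function
        params = PhantomParams()
        cov = coverage_function(params)
        R = params.cup_radius
        expect = R * np.radians(cov(0.0) - params.fossa_polar_deg)
        polys = plane_section(phantom.pelvis_mesh, np.zeros(3), frame.y_axis)
        pts = np.vstack(polys)
        r = np.linalg.norm(pts, axis=1)
        keep = (pts[:, 2] > 1e-6) & (np.abs(r - R) < 1.0)
        arc = pts[keep]
        theta = np.arctan2(arc[:, 2], arc[:, 0])
        order = np.argsort(theta)
        length = np.linalg.norm(np.diff(arc[order], axis=0), axis=1).sum()
        assert length == pytest.approx(expect, rel=0.02)
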