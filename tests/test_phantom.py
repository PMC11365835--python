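"""Synthetic hip phantom: coverage round-trip, determinism, mesh sanity."""

import numpy as np
import pytest

from raoplan.errors import ConfigurationError
from raoplan.geometry import RigidTransform, fit_sphere
from raoplan.measure import asa_profile, clock_to_azimuth, frontal_indices
from raoplan.phantom import (DEFAULT_COVERAGE, ErrorModel, PhantomParams,
                             coverage_function, make_hip_phantom,
                             make_postoperative_model, simulate_digitization)


UNIFORM_COVERAGE = {pos: 100.0 for pos in DEFAULT_COVERAGE}


class TestMakeHipPhantom:
    def test_default_is_dysplastic(self, phantom):
        fi = frontal_indices(phantom)
        # lateral CE analogue ~10 deg, matching a typical preoperative cohort
        assert fi["lateral_ce_deg"] == pytest.approx(10.0, abs=1.0)
        assert 50.0 < fi["ahi_pct"] < 70.0
        assert 15.0 < fi["aro_deg"] < 30.0

    @pytest.mark.parametrize("coverage", [
        DEFAULT_COVERAGE,
        UNIFORM_COVERAGE,
        {"12:00": 95.0, "13:00": 110.0, "15:00": 120.0, "18:00": 140.0,
         "21:00": 120.0, "10:30": 105.0},
    ])
    def test_coverage_round_trip(self, coverage):
        # the measurement stage recovers the requested sector angle at every
        # clock position to within a degree
        params = PhantomParams(coverage_by_clock=coverage)
        model = make_hip_phantom(params)
        cov = coverage_function(params)
        prof = asa_profile(model)
        for pos, val in zip(prof.positions, prof.values_deg):
            assert val == pytest.approx(cov(clock_to_azimuth(pos)), abs=1.0)

    def test_requested_position_exact(self):
        params = PhantomParams(coverage_by_clock={**DEFAULT_COVERAGE,
                                                  "13:00": 95.0})
        prof = asa_profile(make_hip_phantom(params))
        assert prof.value("13:00") == pytest.approx(95.0, abs=1.0)

    def test_determinism(self):
        a = make_hip_phantom(PhantomParams(seed=7))
        b = make_hip_phantom(PhantomParams(seed=7))
        assert np.array_equal(a.pelvis_mesh.vertices, b.pelvis_mesh.vertices)
        assert np.array_equal(a.head_mesh.vertices, b.head_mesh.vertices)
        c = make_hip_phantom(PhantomParams(seed=8))
        assert not np.array_equal(a.pelvis_mesh.vertices, c.pelvis_mesh.vertices)

    def test_head_vertices_on_sphere(self, phantom):
        r = np.linalg.norm(phantom.head_mesh.vertices, axis=1)
        assert np.all(r > 24.0 * 0.99) and np.all(r < 24.0 * 1.01)
        fit = fit_sphere(phantom.head_mesh.vertices)
        assert np.linalg.norm(fit.center) < 1e-6

    def test_mesh_sanity(self, phantom):
        assert len(phantom.pelvis_mesh.vertices) >= 500
        assert np.all(np.isfinite(phantom.pelvis_mesh.vertices))
        assert phantom.pelvis_mesh.area_faces.min() > 1e-6  # no slivers

    def test_severity_scales_lateral_deficit(self):
        mild = make_hip_phantom(PhantomParams(dysplasia_severity=0.5))
        severe = make_hip_phantom(PhantomParams(dysplasia_severity=1.5))
        assert frontal_indices(mild)["lateral_ce_deg"] > \
            frontal_indices(severe)["lateral_ce_deg"]

    @pytest.mark.parametrize("coverage", [
        {"9:00": 100.0, "15:00": 100.0},                      # missing 12:00
        {**UNIFORM_COVERAGE, "12:00": 185.0},                 # out of range
    ])
    def test_invalid_coverage_rejected(self, coverage):
        with pytest.raises(ConfigurationError):
            make_hip_phantom(PhantomParams(coverage_by_clock=coverage))


class TestSimulateDigitization:
    def test_zero_noise_is_identity(self, rng):
        pts = rng.normal(size=(20, 3))
        assert np.array_equal(simulate_digitization(pts, 0.0, 1), pts)

    def test_seed_reproducibility(self, rng):
        pts = rng.normal(size=(20, 3))
        a = simulate_digitization(pts, 0.5, 99)
        b = simulate_digitization(pts, 0.5, 99)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, simulate_digitization(pts, 0.5, 100))

    def test_mean_displacement_matches_chi_distribution(self):
        # |N(0, sd^2 I3)| has mean sd * 2 * sqrt(2/pi); cross-checked against
        # an independently seeded reference sampler
        sd = 0.5
        pts = np.zeros((10_000, 3))
        disp = np.linalg.norm(simulate_digitization(pts, sd, 4) - pts, axis=1)
        analytic = sd * 2.0 * np.sqrt(2.0 / np.pi)
        ref = np.linalg.norm(
            np.random.RandomState(1234).normal(0, sd, size=(10_000, 3)), axis=1)
        assert disp.mean() == pytest.approx(analytic, rel=0.03)
        assert disp.mean() == pytest.approx(ref.mean(), rel=0.03)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_digitization(np.zeros((1, 3)), -0.1, 0)


class TestErrorModel:
    def test_per_axis_rotation_sd(self):
        em = ErrorModel(rot_sd_deg=(3.0, 1.0, 3.0))
        assert em.rot_sd_deg == (3.0, 1.0, 3.0)

    @pytest.mark.parametrize("kw", [
        {"method": "laser"},
        {"rot_sd_deg": -1.0},
        {"rot_sd_deg": (1.0, 2.0)},
        {"acceptance_tol_mm": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            ErrorModel(**kw)


class TestMakePostoperativeModel:
    def test_identity_misplacement_reproduces_plan(self, phantom, plan,
                                                   planning_model):
        post = make_postoperative_model(phantom, plan,
                                        RigidTransform.identity(),
                                        surface_noise_mm=0.0, seed=0,
                                        scanner_pose=RigidTransform.identity())
        assert np.allclose(np.sort(post.pelvis_mesh.vertices, axis=0),
                           np.sort(planning_model.pelvis_mesh.vertices, axis=0),
                           atol=1e-9)
        assert np.allclose(post.landmarks.rim_polyline,
                           planning_model.landmarks.rim_polyline, atol=1e-9)

    def test_scanner_pose_moves_everything_rigidly(self, phantom, plan):
        G = RigidTransform.from_rotvec([10.0, -5.0, 20.0], translation=[30, -10, 5])
        a = make_postoperative_model(phantom, plan, RigidTransform.identity(),
                                     0.0, seed=0, scanner_pose=RigidTransform.identity())
        b = make_postoperative_model(phantom, plan, RigidTransform.identity(),
                                     0.0, seed=0, scanner_pose=G)
        assert np.allclose(b.pelvis_mesh.vertices,
                           G.apply(a.pelvis_mesh.vertices), atol=1e-9)
        assert np.allclose(b.landmarks.ASIS_left,
                           G.apply(a.landmarks.ASIS_left), atol=1e-9)

    def test_surface_noise_only_jitters_pelvis(self, phantom, plan):
        clean = make_postoperative_model(phantom, plan, RigidTransform.identity(),
                                         0.0, seed=5, scanner_pose=RigidTransform.identity())
        noisy = make_postoperative_model(phantom, plan, RigidTransform.identity(),
                                         0.3, seed=5, scanner_pose=RigidTransform.identity())
        d = np.linalg.norm(noisy.pelvis_mesh.vertices - clean.pelvis_mesh.vertices, axis=1)
        assert 0.3 < d.mean() / (2 * np.sqrt(2 / np.pi) * 0.3) < 1.7
        assert np.array_equal(noisy.head_mesh.vertices, clean.head_mesh.vertices)
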