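"""Parametric dysplastic hip phantoms with exactly known coverage geometry.

The phantom idealises a hemipelvis as a spherical-cap acetabulum concentric
with the femoral head: an articular cup shell (head radius + joint gap) with
a central non-articular fossa opening, a 4 mm-thick outer backing shell, and
a radial iliac flange extending far enough proximally for a spherical
osteotomy to pass through it. Because every surface is an analytic function
of the requested per-clock coverage map, sector angles, centre-edge angles
and roof obliquity have closed-form values, which makes the phantom its own
oracle for the measurement pipeline.

A simulated "postoperative" model places the planned fragment with a known
misplacement, jitters the bone surface, and moves everything by a random
scanner pose, so registration and measurement can be exercised end to end
with ground truth in hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np
import trimesh

from .errors import ConfigurationError, PlanningError
from .geometry import RigidTransform
from .measure import clock_to_azimuth
from .model import HipModel, LandmarkSet, mirror_model

if TYPE_CHECKING:  # pragma: no cover
    from .planner import OsteotomyPlan

__all__ = [
    "PhantomParams", "ErrorModel", "DEFAULT_COVERAGE",
    "make_hip_phantom", "make_postoperative_model", "simulate_digitization",
    "coverage_function", "analytic_rim_point",
]

# Dysplastic baseline: superolateral deficit (12:00 sector angle 100 deg, a
# lateral centre-edge analogue of 10 deg) with progressively richer coverage
# toward the anterior, posterior and inferior rim, as in a cup whose roof is
# the deficient part. Keys are clock positions (6:00-18:00 spans the full
# circle through inferior), values are sector angles in degrees.
DEFAULT_COVERAGE: dict[str, float] = {
    "7:30": 140.0,
    "9:00": 123.0,
    "10:30": 115.0,
    "12:00": 100.0,
    "13:30": 118.0,
    "15:00": 127.0,
    "16:30": 137.0,
    "18:00": 145.0,
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the synthetic dysplastic hip (mm / degrees).

    ``dysplasia_severity`` scales the superolateral coverage deficit: one
    unit above (below) 1.0 removes (adds) 15 degrees of sector angle at
    12:00, tapering as cos(azimuth) toward 9:00/3:00.
    """

    head_radius: float = 24.0
    coverage_by_clock: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE))
    dysplasia_severity: float = 1.0
    mesh_resolution: float = 2.0
    seed: int = 0
    joint_gap_mm: float = 2.0
    fossa_polar_deg: float = 30.0
    shell_thickness_mm: float = 4.0
    collar_radius_mm: float = 52.0
    wing_length_mm: float = 38.0
    wing_center_deg: float = -35.0
    wing_halfwidth_deg: float = 95.0
    wing_twist_deg: float = 30.0
    app_offset_mm: float = 15.0
    bilateral_separation_mm: float = 180.0
    koehler_offset_mm: float = 45.0
    side: str = "right"

    def __post_init__(self):
        if self.head_radius <= 0:
            raise ConfigurationError("head_radius must be positive")
        if self.mesh_resolution <= 0:
            raise ConfigurationError("mesh_resolution must be positive")
        if "12:00" not in self.coverage_by_clock or len(self.coverage_by_clock) < 4:
            raise ConfigurationError(
                "coverage_by_clock must contain 12:00 and at least 4 positions")
        for pos, val in self.coverage_by_clock.items():
            if not 0.0 < val < 180.0:
                raise ConfigurationError(
                    f"coverage at {pos} must lie in (0, 180) deg, got {val}")

    @property
    def cup_radius(self) -> float:
        return self.head_radius + self.joint_gap_mm


def coverage_function(params: PhantomParams):
    """Periodic piecewise-linear sector-angle function az_deg -> ASA_deg.

    Interpolates the coverage map over azimuth (12:00 = 0, anterior positive)
    and applies the dysplasia-severity adjustment.
    """
    anchors = sorted((clock_to_azimuth(pos), float(val))
                     for pos, val in params.coverage_by_clock.items())
    az = np.array([a for a, _ in anchors])
    val = np.array([v for _, v in anchors])
    if np.max(np.diff(np.r_[az, az[0] + 360.0])) > 120.0:
        raise ConfigurationError("coverage map leaves an azimuth gap > 120 deg")
    az_ext = np.r_[az[-1] - 360.0, az, az[0] + 360.0]
    val_ext = np.r_[val[-1], val, val[0]]
    sev = params.dysplasia_severity

    def cov(azimuth_deg):
        a = (np.asarray(azimuth_deg, float) + 180.0) % 360.0 - 180.0
        base = np.interp(a, az_ext, val_ext)
        out = base - 15.0 * (sev - 1.0) * np.maximum(np.cos(np.radians(a)), 0.0)
        return out if out.ndim else float(out)

    # validate against the fossa opening
    test = cov(np.linspace(-180.0, 180.0, 721))
    if np.any(test <= params.fossa_polar_deg + 5.0):
        raise ConfigurationError("coverage must exceed the fossa opening by >= 5 deg")
    if np.any(test >= 178.0):
        raise ConfigurationError("coverage approaches the medial pole; reduce it")
    return cov


def _direction(az_deg, polar_deg):
    """Unit direction at clock azimuth az (about x) and polar angle from +x."""
    az = np.radians(np.asarray(az_deg, float))
    po = np.radians(np.asarray(polar_deg, float))
    return np.stack([np.cos(po),
                     np.sin(po) * np.sin(az),
                     np.sin(po) * np.cos(az)], axis=-1)


def analytic_rim_point(params: PhantomParams, az_deg: float) -> np.ndarray:
    """Closed-form rim point of the (right-convention) phantom at an azimuth,
    relative to the operative head centre at the origin."""
    cov = coverage_function(params)
    return params.cup_radius * _direction(az_deg, cov(az_deg))


class _MeshBuilder:
    """Accumulates rows of a wrapped parametric grid into one indexed mesh."""

    def __init__(self):
        self.vertices: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []

    def add_row(self, points: np.ndarray) -> np.ndarray:
        idx = np.arange(len(self.vertices), len(self.vertices) + len(points))
        self.vertices.extend(np.asarray(points, float))
        return idx

    def connect(self, row_a: np.ndarray, row_b: np.ndarray):
        n = len(row_a)
        for j in range(n):
            k = (j + 1) % n
            self.faces.append((row_a[j], row_a[k], row_b[j]))
            self.faces.append((row_b[j], row_a[k], row_b[k]))

    def strip(self, rows: list[np.ndarray]):
        for a, b in zip(rows[:-1], rows[1:]):
            self.connect(a, b)

    def build(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=np.array(self.vertices),
                               faces=np.array(self.faces), process=False)


def make_hip_phantom(params: PhantomParams | None = None) -> HipModel:
    """Generate the parametric dysplastic hip model.

    Deterministic: identical parameters (including ``seed``) give
    bit-identical vertex arrays. The acetabular rim polyline, head centres,
    APP landmarks and Koehler-line proxy are emitted consistently with the
    generated surfaces, so measured sector angles reproduce the requested
    coverage map to within mesh interpolation (about a degree).
    """
    params = params or PhantomParams()
    cov = coverage_function(params)
    R = params.cup_radius
    res = params.mesh_resolution
    thick = params.shell_thickness_mm
    # peri-acetabular collar all the way around (the osteotomy sphere must
    # pass through bone at every azimuth) plus a slab-like iliac wing over the
    # posterosuperior azimuths only — a hemipelvis is nowhere near a surface
    # of revolution, and the wing's asymmetry is what anchors registration
    if params.collar_radius_mm <= R + thick + 10.0:
        raise ConfigurationError("collar too small for an osteotomy; increase "
                                 "collar_radius_mm")

    # The parametric grid is jittered (deterministically, from the seed) so
    # the triangulation carries no rotational self-similarity: every vertex
    # still lies exactly on the analytic surface, but a rotated copy of the
    # mesh can only coincide with itself at the true pose — as with real
    # segmented surfaces, whose vertices are irregular. Boundary rows (fossa
    # edge, rim, shell junctions) are kept exact.
    rng = np.random.default_rng(params.seed)
    n_az = max(48, int(np.ceil(2.0 * np.pi * R / res)))
    az_step = 360.0 / n_az
    az = (-180.0 + az_step * np.arange(n_az)
          + rng.uniform(-0.35, 0.35, n_az) * az_step)
    A = cov(az)  # rim polar angle per azimuth column
    fossa = params.fossa_polar_deg

    span_max = np.radians(float(np.max(A)) - fossa)
    n_cup = max(8, int(np.ceil(span_max * R / res)) + 1)
    u = np.linspace(0.0, 1.0, n_cup)

    def jitter_rows(base: np.ndarray) -> np.ndarray:
        """(n_rows, n_az) row fractions with interior rows jittered."""
        rows = np.repeat(base[:, None], n_az, axis=1)
        if len(base) > 2:
            step = np.diff(base)[:, None]
            rows[1:-1] += rng.uniform(-0.3, 0.3, (len(base) - 2, n_az)) \
                * np.minimum(step[:-1], step[1:])
        return rows

    # Low-frequency radial waviness (sub-millimetre, like cartilage and
    # segmentation relief) on the cup and backing shells: a perfect sphere
    # carries no registration information, so without it the shells slide
    # freely under ICP. Feathered to zero at the fossa edge and rim so the
    # analytic rim, coverage and roof-obliquity oracles are untouched.
    def waviness(polar_deg: np.ndarray, az_deg: np.ndarray) -> np.ndarray:
        a = np.radians(az_deg)
        p = np.radians(polar_deg)
        return (0.5 * np.cos(2 * a + 3 * p + 0.7)
                + 0.4 * np.cos(3 * a - 2 * p + 2.1)
                + 0.3 * np.cos(a + 5 * p + 4.0)
                + 0.25 * np.cos(5 * a + 2 * p + 1.3))

    u_rows = jitter_rows(u)
    b = _MeshBuilder()
    # articular cup: fossa edge -> rim at the cup radius
    cup_rows = []
    for ui in u_rows:
        polar = fossa + ui * (A - fossa)
        r_eff = R + np.sin(np.pi * np.clip(ui, 0.0, 1.0)) * waviness(polar, az)
        cup_rows.append(b.add_row(r_eff[:, None] * _direction(az, polar)))
    # radial run at the rim directions: lip through backing radius, then the
    # collar and the iliac wing (a raised-cosine lobe of extra radial extent
    # over the posterosuperior azimuths)
    rim_dirs = _direction(az, A)
    d_az = (az - params.wing_center_deg + 180.0) % 360.0 - 180.0
    lobe = np.where(np.abs(d_az) < params.wing_halfwidth_deg,
                    np.cos(np.radians(d_az / params.wing_halfwidth_deg * 90.0)) ** 2,
                    0.0)
    r_out = params.collar_radius_mm + params.wing_length_mm * lobe
    r_lip = np.linspace(R, R + thick, max(2, int(np.ceil(thick / res)) + 1))
    lip_rows = jitter_rows(r_lip)[1:]
    n_fl = max(2, int(np.ceil((np.max(r_out) - R - thick) / res)) + 1)
    fl_frac = jitter_rows(np.linspace(0.0, 1.0, n_fl))[1:]
    flange_rows = (R + thick) + fl_frac * (r_out - R - thick)
    # tubercle-like ridges at asymmetric azimuths (crest landmarks); they
    # feather in away from the acetabular shell and leave every measurement
    # surface untouched
    ridge = np.zeros(n_az)
    for az0, width, amp in ((-150.0, 12.0, 7.0), (-60.0, 14.0, 5.0),
                            (20.0, 11.0, 8.0), (120.0, 16.0, 6.0)):
        d = (az - az0 + 180.0) % 360.0 - 180.0
        ridge += amp * np.exp(-0.5 * (d / width) ** 2)
    feather = np.clip((flange_rows - (R + thick + 4.0)) / 6.0, 0.0, 1.0)
    flange_rows = flange_rows + feather * ridge
    # the wing twists out of the radial cone (anterior column bends one way,
    # posterior the other, as the iliac wing does); past the collar the polar
    # angle of a wing ray drifts with radius, so no rotation about the
    # mediolateral axis can slide the wing over itself
    twist_az = params.wing_twist_deg * np.sin(np.radians(
        np.clip(d_az / params.wing_halfwidth_deg, -1.0, 1.0) * 180.0)) * (lobe > 0)
    radial_rows = [cup_rows[-1]]
    for rr in np.vstack([lip_rows, flange_rows]):
        bfrac = np.clip((rr - params.collar_radius_mm)
                        / max(params.wing_length_mm, 1.0), 0.0, 1.0)
        polar_r = A + twist_az * bfrac
        radial_rows.append(b.add_row(rr[:, None] * _direction(az, polar_r)))
    backing_start = radial_rows[len(lip_rows)]  # row at radius R + thick
    # outer backing shell: rim back down to the fossa edge
    backing_rows = [backing_start]
    for ui in jitter_rows(u)[1:]:
        polar = A + ui * (fossa - A)
        r_eff = (R + thick
                 + np.sin(np.pi * np.clip(ui, 0.0, 1.0)) * waviness(polar, -az))
        backing_rows.append(b.add_row(r_eff[:, None] * _direction(az, polar)))
    b.strip(cup_rows)
    b.strip(radial_rows)
    b.strip(backing_rows)
    pelvis = b.build()

    head = trimesh.creation.icosphere(subdivisions=3, radius=params.head_radius)
    head = trimesh.Trimesh(vertices=head.vertices.copy(), faces=head.faces.copy(),
                           process=False)

    n_rim = 240
    rim_az = -180.0 + 360.0 * np.arange(n_rim) / n_rim
    rim = R * _direction(rim_az, cov(rim_az))

    sep = params.bilateral_separation_mm
    app = params.app_offset_mm
    landmarks = LandmarkSet(
        ASIS_right=np.array([-25.0, app, 95.0]),
        ASIS_left=np.array([sep + 25.0, app, 95.0]),
        pubic_right=np.array([sep / 2 - 15.0, app, -15.0]),
        pubic_left=np.array([sep / 2 + 15.0, app, -15.0]),
        head_center_right=np.zeros(3),
        head_center_left=np.array([sep, 0.0, 0.0]),
        koehler_a=np.array([params.koehler_offset_mm, 0.0, -40.0]),
        koehler_b=np.array([params.koehler_offset_mm, 0.0, 60.0]),
        rim_polyline=rim,
    )
    model = HipModel(pelvis_mesh=pelvis, head_mesh=head, landmarks=landmarks,
                     side="right")
    if params.side == "left":
        model = mirror_model(model)
    return model


# ---------------------------------------------------------------------------
# simulated intraoperative / postoperative data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Stochastic model of intraoperative fragment placement and its check.

    ``rot_sd_deg``/``trans_sd_mm`` are per-axis standard deviations of the
    attempted placement error (a rotation about the planned head centre plus
    a translation); a scalar applies to all three axes, a 3-sequence gives
    (mediolateral, anteroposterior, craniocaudal) separately.
    ``digitization_sd_mm`` is isotropic pointer noise; ``acceptance_tol_mm``
    is the distance tolerance of the intraoperative confirmation step. All
    values are simulation parameters, not clinical measurements.
    """

    method: str = "fiducial"  # {"previous", "fiducial"}
    rot_sd_deg: float | tuple[float, float, float] = 1.0
    trans_sd_mm: float | tuple[float, float, float] = 1.0
    digitization_sd_mm: float = 0.3
    acceptance_tol_mm: float = 2.0

    def __post_init__(self):
        if self.method not in ("previous", "fiducial"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        for name in ("rot_sd_deg", "trans_sd_mm"):
            val = np.atleast_1d(np.asarray(getattr(self, name), float))
            if val.shape not in ((1,), (3,)) or np.any(val < 0):
                raise ConfigurationError(
                    f"{name} must be a scalar or 3-sequence of values >= 0")
            object.__setattr__(self, name,
                               float(val[0]) if len(val) == 1 else tuple(val))
        if self.digitization_sd_mm < 0:
            raise ConfigurationError("digitization_sd_mm must be >= 0")
        if self.acceptance_tol_mm <= 0:
            raise ConfigurationError("acceptance_tol_mm must be positive")

    @staticmethod
    def previous_default() -> "ErrorModel":
        """Surface-touch confirmation: looser effective rotational control."""
        return ErrorModel(method="previous", rot_sd_deg=3.0)

    @staticmethod
    def fiducial_default() -> "ErrorModel":
        """Four-fiducial confirmation: tighter rotational control."""
        return ErrorModel(method="fiducial", rot_sd_deg=1.0)


def simulate_digitization(points: np.ndarray, sd_mm: float, seed: int) -> np.ndarray:
    """Isotropic Gaussian pointer noise on digitized points; seeded."""
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    pts = np.array(points, float, copy=True)
    if sd_mm == 0:
        return pts
    rng = np.random.default_rng(seed)
    return pts + rng.normal(0.0, sd_mm, size=pts.shape)


def make_postoperative_model(model: HipModel, plan: "OsteotomyPlan",
                             misplacement: RigidTransform,
                             surface_noise_mm: float = 0.0,
                             seed: int = 0,
                             scanner_pose: RigidTransform | None = None) -> HipModel:
    """Synthesize the 1-week postoperative surface model.

    The fragment (and the femoral head, which follows the reoriented
    acetabulum) is placed at ``misplacement ∘ planned``, i.e. the
    misplacement perturbs the planned pose in patient coordinates. The
    remaining pelvis is unchanged up to isotropic vertex jitter of SD
    ``surface_noise_mm``; finally the whole model is moved by a scanner-pose
    transform (random from ``seed`` unless given) so the registration stage
    has real work to do.
    """
    if len(plan.fragment_mesh.vertices) + len(plan.remainder_mesh.vertices) < \
            len(model.pelvis_mesh.vertices):
        raise PlanningError("plan does not correspond to this model")
    rng = np.random.default_rng(seed)
    F = misplacement @ plan.reorientation
    frag = F.transform_mesh(plan.fragment_mesh)
    pelvis = trimesh.util.concatenate(
        trimesh.Trimesh(vertices=plan.remainder_mesh.vertices.copy(),
                        faces=plan.remainder_mesh.faces.copy(), process=False),
        frag)
    head = F.transform_mesh(model.head_mesh)
    lm = model.landmarks
    c_op = model.operative_head_center
    if model.side == "right":
        lm = lm.replace(head_center_right=F.apply(c_op))
    else:
        lm = lm.replace(head_center_left=F.apply(c_op))
    lm = lm.replace(rim_polyline=F.apply(lm.rim_polyline))

    if surface_noise_mm > 0:
        pelvis = trimesh.Trimesh(
            vertices=pelvis.vertices + rng.normal(0.0, surface_noise_mm,
                                                  size=pelvis.vertices.shape),
            faces=pelvis.faces, process=False)
    G = scanner_pose if scanner_pose is not None else RigidTransform.random(
        rng, max_rotation_deg=20.0, max_translation_mm=30.0)
    return HipModel(pelvis_mesh=G.transform_mesh(pelvis),
                    head_mesh=G.transform_mesh(head),
                    landmarks=lm.transformed(G),
                    side=model.side)
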