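"""Clock-face sector-angle measurement of acetabular coverage.

The acetabular sector angle (ASA) at a clock position is the angle, inside
the radial plane of that position, between the mediolateral x-axis and the
line from the femoral head centre to the acetabular rim. The clock face is
anchored to the anterior pelvic plane: 12:00 cephalad, 3:00 anterior, 9:00
posterior; one radial plane every 30 clock minutes is a 15 degree step about
the x-axis. ΔASA (postoperative minus planned, degrees) is the accuracy
index for fragment reorientation: positive means overcorrection, negative
under-correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import AnatomicalFrame, build_frame, fit_sphere, plane_section
from .model import HipModel, ensure_right

__all__ = [
    "ClockFace", "ASAProfile", "DeltaProfile",
    "clock_to_azimuth", "azimuth_to_clock",
    "build_clock_face", "measure_asa", "asa_profile", "delta_profile",
    "roof_obliquity", "frontal_indices",
]

log = logging.getLogger("raoplan.measure")


# ---------------------------------------------------------------------------
# clock arithmetic
# ---------------------------------------------------------------------------

def clock_to_azimuth(position: str | float) -> float:
    """Azimuth about the x-axis in degrees: 12:00 -> 0 (cephalad), 3:00/15:00
    -> +90 (anterior), 9:00 -> -90 (posterior), 6:00/18:00 -> 180."""
    if isinstance(position, str):
        hh, mm = position.split(":")
        hours = int(hh) + int(mm) / 60.0
    else:
        hours = float(position)
    az = (hours - 12.0) * 30.0
    az = ((az + 180.0) % 360.0) - 180.0
    return 180.0 if az == -180.0 else az


def azimuth_to_clock(az_deg: float) -> str:
    az_deg = ((az_deg + 180.0) % 360.0) - 180.0
    if az_deg == -180.0:
        az_deg = 180.0
    hours = az_deg / 30.0 + 12.0
    hours %= 24.0
    hh = int(hours)
    mm = int(round((hours - hh) * 60.0))
    if mm == 60:
        hh, mm = hh + 1, 0
    return f"{hh}:{mm:02d}"


@dataclass(frozen=True)
class ClockFace:
    """Ordered set of radial measurement planes about the mediolateral axis."""

    frame: AnatomicalFrame
    positions: tuple[str, ...]
    step_minutes: int = 30

    def azimuth(self, position: str | float) -> float:
        return clock_to_azimuth(position)

    def direction(self, position: str | float) -> np.ndarray:
        """In-plane unit vector of the clock position (world coordinates)."""
        az = np.radians(self.azimuth(position))
        return np.cos(az) * self.frame.z_axis + np.sin(az) * self.frame.y_axis

    def plane_normal(self, position: str | float) -> np.ndarray:
        """Unit normal of the radial plane (x-axis crossed with direction)."""
        az = np.radians(self.azimuth(position))
        return np.sin(az) * self.frame.z_axis - np.cos(az) * self.frame.y_axis


def build_clock_face(frame: AnatomicalFrame, step_minutes: int = 30,
                     start: str = "9:00", end: str = "15:00") -> ClockFace:
    """Clock face from ``start`` to ``end`` (through 12:00) every
    ``step_minutes``; the default is the 13-plane 9:00-to-3:00 superior arc,
    radial planes every 15 degrees."""
    az0 = clock_to_azimuth(start)
    az1 = clock_to_azimuth(end)
    span = az1 - az0
    if span <= 0:
        raise ConfigurationError("end position must lie after start (through 12:00)")
    step_deg = step_minutes * 0.5
    n_steps = span / step_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(
            f"step of {step_minutes} min does not divide the {start}->{end} span")
    labels = tuple(azimuth_to_clock(az0 + i * step_deg)
                   for i in range(int(round(n_steps)) + 1))
    return ClockFace(frame=frame, positions=labels, step_minutes=step_minutes)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASAProfile:
    positions: tuple[str, ...]
    values_deg: np.ndarray
    source: str = "preoperative"  # {preoperative, planning, postoperative}
    head_center: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values_deg, float)
        if len(v) != len(self.positions):
            raise ConfigurationError("one ASA value per clock position required")
        object.__setattr__(self, "values_deg", v)

    def value(self, position: str) -> float:
        return float(self.values_deg[self.positions.index(position)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": list(self.positions),
                             "value_deg": self.values_deg,
                             "source": self.source})


@dataclass(frozen=True)
class DeltaProfile:
    """Per-position ΔASA = postoperative - planned (degrees)."""

    positions: tuple[str, ...]
    values_deg: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values_deg, float)
        if len(v) != len(self.positions):
            raise ConfigurationError("one ΔASA value per clock position required")
        object.__setattr__(self, "values_deg", v)

    def value(self, position: str) -> float:
        return float(self.values_deg[self.positions.index(position)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": list(self.positions),
                             "delta_deg": self.values_deg})


# ---------------------------------------------------------------------------
# rim intersection machinery
# ---------------------------------------------------------------------------

def _wrap180(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def rim_crossings(rim: np.ndarray, center: np.ndarray, frame: AnatomicalFrame,
                  azimuth_deg: float) -> list[np.ndarray]:
    """Intersections of the closed rim loop with the radial half-plane at the
    given azimuth (world points), linearly interpolated along rim segments."""
    local = frame.rotation_matrix.T @ (np.asarray(rim, float) - center).T
    x, y, z = local
    az = np.degrees(np.arctan2(y, z))
    delta = _wrap180(az - azimuth_deg)
    out = []
    n = len(rim)
    for i in range(n):
        j = (i + 1) % n
        di, dj = delta[i], delta[j]
        if abs(di) >= 90.0 or abs(dj) >= 90.0:
            continue  # wrong side of the clock face
        if di == 0.0:
            out.append(np.asarray(rim[i], float))
        elif di * dj < 0.0:
            t = di / (di - dj)
            out.append(np.asarray(rim[i], float) * (1 - t) + np.asarray(rim[j], float) * t)
    return out


def _rim_point(rim, center, frame, azimuth_deg, position="?"):
    pts = rim_crossings(rim, center, frame, azimuth_deg)
    if not pts:
        log.info("no rim intersection in the %s half-plane; value missing", position)
        return None
    if len(pts) > 1:
        log.info("rim crosses the %s half-plane %d times; keeping the point "
                 "farthest from the head centre", position, len(pts))
        pts.sort(key=lambda p: np.linalg.norm(p - center))
    return pts[-1]


def measure_asa(model: HipModel, clock_face: ClockFace | None = None,
                position: str = "12:00", head_center: np.ndarray | None = None,
                rim: np.ndarray | None = None) -> float:
    """ASA (degrees, in [0, 180]) at one clock position; NaN when the rim
    does not cross the radial half-plane."""
    m = ensure_right(model)
    if clock_face is None:
        clock_face = build_clock_face(build_frame(m.landmarks, m.side))
    frame = clock_face.frame
    center = (np.asarray(head_center, float) if head_center is not None
              else fit_sphere(m.head_mesh.vertices).center)
    rim = m.landmarks.rim_polyline if rim is None else np.asarray(rim, float)
    p = _rim_point(rim, center, frame, clock_face.azimuth(position), position)
    if p is None:
        return float("nan")
    v = p - center
    return float(np.degrees(np.arctan2(v @ clock_face.direction(position),
                                       v @ frame.x_axis)))


def asa_profile(model: HipModel, clock_face: ClockFace | None = None,
                head_center: np.ndarray | None = None,
                rim: np.ndarray | None = None,
                source: str = "preoperative") -> ASAProfile:
    """ASA at every clock-face position.

    The head centre defaults to the best-fit sphere of the model's femoral
    head mesh; planning models should pass the planned head centre (the
    preoperative fitted centre carried through the reorientation transform).
    """
    m = ensure_right(model)
    if clock_face is None:
        clock_face = build_clock_face(build_frame(m.landmarks, m.side))
    center = (np.asarray(head_center, float) if head_center is not None
              else fit_sphere(m.head_mesh.vertices).center)
    values = [measure_asa(m, clock_face, pos, head_center=center, rim=rim)
              for pos in clock_face.positions]
    return ASAProfile(positions=clock_face.positions, values_deg=np.array(values),
                      source=source, head_center=center)


def delta_profile(post: ASAProfile, plan: ASAProfile) -> DeltaProfile:
    if post.positions != plan.positions:
        raise ConfigurationError("profiles were measured on different clock faces")
    return DeltaProfile(positions=post.positions,
                        values_deg=post.values_deg - plan.values_deg)


# ---------------------------------------------------------------------------
# frontal-plane analogues
# ---------------------------------------------------------------------------

def roof_obliquity(mesh, frame: AnatomicalFrame, head_center: np.ndarray,
                   rim: np.ndarray) -> float:
    """Acetabular roof obliquity (ARO, degrees) in the mid-frontal plane.

    The pelvis is sectioned with the plane through the head centre spanned by
    the x and z axes; section points on the superior articular arc (radius
    within 5% of the 12:00 rim distance) are kept, and the chord from the
    medial roof edge to the lateral rim is compared with the horizontal
    x-axis. Positive values mean an upsloping (dysplastic) roof.
    """
    center = np.asarray(head_center, float)
    r12 = _rim_point(rim, center, frame, 0.0, "12:00")
    if r12 is None:
        return float("nan")
    rho = np.linalg.norm(r12 - center)
    pts = []
    for poly in plane_section(mesh, center, frame.y_axis):
        pts.append(poly)
    if not pts:
        return float("nan")
    local = (np.vstack(pts) - center) @ frame.rotation_matrix
    x, z = local[:, 0], local[:, 2]
    radius = np.hypot(x, z)
    keep = (z > 1e-6) & (radius <= 1.05 * rho)
    if keep.sum() < 2:
        return float("nan")
    theta = np.degrees(np.arctan2(z[keep], x[keep]))
    order = np.argsort(theta)
    theta_s = theta[order]
    gaps = np.diff(theta_s)
    gap_tol = max(2.0, 5.0 * float(np.median(gaps)) if len(gaps) else 2.0)
    # contiguous runs; the roof is the run containing the lateral rim (max theta)
    breaks = np.flatnonzero(gaps > gap_tol)
    start = breaks[-1] + 1 if len(breaks) else 0
    run = order[start:]
    if len(run) < 5 or np.ptp(theta_s[start:]) < 10.0:
        return float("nan")  # arc too short to define a roof chord
    xs, zs = x[keep][run], z[keep][run]
    th_run = np.degrees(np.arctan2(zs, xs))
    # medial roof edge: the section polyline terminates exactly on the fossa
    # boundary, so the run's lowest-angle point is a true edge crossing;
    # lateral rim: the rim-polyline crossing (exact), not a section vertex
    i_med = int(np.argmin(th_run))
    med = np.array([xs[i_med], zs[i_med]])
    lat_local = (r12 - center) @ frame.rotation_matrix
    lat = np.array([lat_local[0], lat_local[2]])
    if np.degrees(np.arctan2(lat[1], lat[0])) <= th_run[i_med] + 1e-9:
        return float("nan")
    v = lat - med
    if -v[0] < 0:
        v = -v
    aro = float(np.degrees(np.arctan2(v[1], -v[0])))
    # outside the anatomically meaningful regime: treat as unmeasurable
    return aro if abs(aro) <= 60.0 else float("nan")


def frontal_indices(model: HipModel, frame: AnatomicalFrame | None = None,
                    head_center: np.ndarray | None = None,
                    rim: np.ndarray | None = None) -> dict[str, float]:
    """Frontal-projection coverage analogues computed on the 3D model.

    Returns lateral/anterior centre-edge angles (ASA at 12:00 / 3:00 minus
    90), the mid-frontal roof obliquity, the acetabular head index (percent
    of the mediolateral head width covered in frontal projection) and the
    perpendicular distance from the head centre to the Koehler-line proxy.
    """
    m = ensure_right(model)
    if frame is None:
        frame = build_frame(m.landmarks, m.side)
    fit = fit_sphere(m.head_mesh.vertices)
    center = np.asarray(head_center, float) if head_center is not None else fit.center
    rim = m.landmarks.rim_polyline if rim is None else np.asarray(rim, float)
    face = build_clock_face(frame)
    asa12 = measure_asa(m, face, "12:00", head_center=center, rim=rim)
    asa15 = measure_asa(m, face, "15:00", head_center=center, rim=rim)
    aro = roof_obliquity(m.pelvis_mesh, frame, center, rim)

    r_head = fit.radius
    p12 = _rim_point(rim, center, frame, 0.0, "12:00")
    if p12 is None:
        ahi = float("nan")
    else:
        x_lat = float((p12 - center) @ frame.x_axis)
        covered = r_head - max(x_lat, -r_head)
        ahi = float(np.clip(100.0 * covered / (2.0 * r_head), 0.0, 100.0))

    a, b = m.landmarks.koehler_a, m.landmarks.koehler_b
    d = np.linalg.norm(np.cross(b - a, center - a)) / np.linalg.norm(b - a)
    return {"lateral_ce_deg": asa12 - 90.0,
            "anterior_ce_deg": asa15 - 90.0,
            "aro_deg": aro,
            "ahi_pct": ahi,
            "koehler_mm": float(d)}
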