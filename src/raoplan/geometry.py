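"""Rigid-body and mesh geometry primitives shared by every pipeline stage.

Conventions: all lengths in millimetres, all angles in degrees unless a name
says otherwise. Rotations are proper (det = +1); reflections are never
produced by the estimators here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.optimize import least_squares

from .errors import DegenerateInputError

__all__ = [
    "RigidTransform",
    "Sphere",
    "SphereFit",
    "AnatomicalFrame",
    "ICPResult",
    "MeshDistance",
    "fit_sphere",
    "kabsch",
    "icp",
    "robust_icp",
    "centroid_align",
    "closest_point_on_mesh",
    "build_frame",
    "plane_section",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a rigid transform")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_rotvec(rotvec_deg: Sequence[float],
                    center: Sequence[float] | None = None,
                    translation: Sequence[float] | None = None) -> "RigidTransform":
        """Rotation given as an axis-angle vector in degrees, optionally about
        a ``center`` point, optionally followed by a ``translation``."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        c = np.zeros(3) if center is None else np.asarray(center, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return RigidTransform(R, c - R @ c + t)

    @staticmethod
    def random(rng: np.random.Generator,
               max_rotation_deg: float = 30.0,
               max_translation_mm: float = 30.0) -> "RigidTransform":
        """Uniform random axis, uniform angle in (0, max], uniform translation
        in the cube [-max, max]^3 — used to emulate arbitrary scanner pose."""
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, max_rotation_deg)
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        return RigidTransform.from_rotvec(axis * angle, translation=t)

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first: (self∘other)(p)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation component."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    def transform_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.apply(mesh.vertices),
                               faces=mesh.faces.copy(), process=False)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.abs(self.rotation - np.eye(3)).max() < tol
                and np.abs(self.translation).max() < tol)


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class SphereFit:
    """Best-fit sphere plus the RMS of the signed radial residuals (mm)."""
    sphere: Sphere
    rms_residual: float

    @property
    def center(self) -> np.ndarray:
        return self.sphere.center

    @property
    def radius(self) -> float:
        return self.sphere.radius


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed pelvic measurement frame.

    Origin: operative femoral head centre. ``x_axis``: mediolateral, through
    the bilateral head centres, pointing toward the contralateral hip (the
    reference direction for sector-angle measurement). ``z_axis``: cephalad
    within the anterior pelvic plane (APP), perpendicular to x. ``y_axis``:
    z × x — anterior for a right-convention model.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        R = self.rotation_matrix
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame is not right-handed")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.rotation_matrix

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation_matrix.T + self.origin


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere through a point cloud.

    Algebraic (linear) fit followed by geometric Gauss–Newton refinement of
    the radial residuals ``|p - c| - r``. Requires at least four non-coplanar
    points; raises :class:`DegenerateInputError` otherwise.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise DegenerateInputError("sphere fit needs >= 4 points in 3D")
    # coplanarity check on the centered cloud
    centered = p - p.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("points are coplanar; sphere is undetermined")

    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def residual(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    res = least_squares(residual, np.r_[c0, r0], method="lm")
    c, r = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return SphereFit(Sphere(c, r), rms)


# ---------------------------------------------------------------------------
# rigid point-set alignment
# ---------------------------------------------------------------------------

def kabsch(src: np.ndarray, dst: np.ndarray,
           labels: Sequence[str] | None = None) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares rigid transform T minimising Σ‖T(src_i) − dst_i‖².

    SVD solution with the determinant corrected to +1 so a reflection is
    never returned. Returns the transform and the per-point residual norms
    (mm). Collinear source points raise :class:`DegenerateInputError`.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise DegenerateInputError("kabsch needs matching (n, 3) point sets")
    if len(src) < 3:
        raise DegenerateInputError("kabsch needs >= 3 correspondences")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        what = "source points" if labels is None else f"points {list(labels)}"
        raise DegenerateInputError(f"{what} are collinear; rotation is undetermined")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dc - R @ sc
    T = RigidTransform(R, t)
    residuals = np.linalg.norm(T.apply(src) - dst, axis=1)
    return T, residuals


def centroid_align(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Translation-only initial guess mapping the source centroid to the
    destination centroid (the standard ICP initialisation here)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    return RigidTransform(np.eye(3), dst.mean(axis=0) - src.mean(axis=0))


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    final_mse: float
    iterations: int
    converged_by: str  # {"mse_tol", "stall", "max_iter"}
    converged: bool = field(default=True)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, trimesh.Trimesh):
        return np.asarray(obj.vertices, float)
    return np.asarray(obj, float)


def icp(src, dst, init: RigidTransform | None = None,
        mse_tol: float = 1.0e-5, max_iter: int = 200,
        max_points: int = 50_000, seed: int = 0) -> ICPResult:
    """Point-to-point iterative closest point registration.

    Alternates nearest-vertex correspondence (KD-tree; ties broken toward the
    lowest vertex index) with a full Kabsch re-solve. Terminates when the mean
    squared nearest-neighbour distance (mm²) drops to ``mse_tol`` (default
    1e-5), when the improvement per iteration falls below 1e-12, or at
    ``max_iter``. Vertex sets larger than ``max_points`` are subsampled with
    a seeded generator so results are reproducible.
    """
    src_pts = _as_points(src)
    dst_pts = _as_points(dst)
    if len(src_pts) == 0 or len(dst_pts) == 0:
        raise DegenerateInputError("icp requires non-empty point sets")
    if mse_tol <= 0:
        raise ValueError("mse_tol must be positive")
    rng = np.random.default_rng(seed)
    if len(src_pts) > max_points:
        src_pts = src_pts[rng.choice(len(src_pts), max_points, replace=False)]
    if len(dst_pts) > max_points:
        dst_pts = dst_pts[rng.choice(len(dst_pts), max_points, replace=False)]

    tree = cKDTree(dst_pts)
    T = init if init is not None else centroid_align(src_pts, dst_pts)
    prev_mse = np.inf
    converged_by = "max_iter"
    iterations = 0
    mse = np.inf
    for it in range(max_iter):
        moved = T.apply(src_pts)
        dist, idx = tree.query(moved)
        mse = float(np.mean(dist ** 2))
        iterations = it
        if mse <= mse_tol:
            converged_by = "mse_tol"
            break
        if prev_mse - mse < 1e-12:
            converged_by = "stall"
            break
        prev_mse = mse
        T, _ = kabsch(src_pts, dst_pts[idx])
    return ICPResult(transform=T, final_mse=mse, iterations=iterations,
                     converged_by=converged_by,
                     converged=converged_by != "max_iter")


def robust_icp(src, dst_mesh: trimesh.Trimesh, init: RigidTransform | None = None,
               mse_tol: float = 1.0e-5, max_iter: int = 200,
               refine_points: int = 2000, refine_max_iter: int = 150,
               seed: int = 0) -> ICPResult:
    """Vertex ICP with a surface-projection escape stage.

    Identically triangulated surfaces can lock vertex-to-vertex ICP into a
    lattice-shifted fixpoint (every vertex pairs with a neighbouring grid
    column, and the update returns the same pose). When the vertex stage
    stalls above ``mse_tol``, a refinement stage re-solves with
    correspondences projected onto the destination *surface* (a seeded
    subsample of the source for speed), which has no such fixpoints; a final
    vertex pass then reports the standard vertex-to-vertex MSE.
    """
    src_pts = _as_points(src)
    first = icp(src_pts, dst_mesh.vertices, init=init, mse_tol=mse_tol,
                max_iter=max_iter, seed=seed)
    if first.final_mse <= mse_tol:
        return first
    rng = np.random.default_rng(seed)
    pts = src_pts
    if len(pts) > refine_points:
        pts = pts[rng.choice(len(pts), refine_points, replace=False)]
    surface = MeshDistance(dst_mesh, k=6)
    T = first.transform
    prev = np.inf
    it2 = 0
    for it2 in range(refine_max_iter):
        near, dist = surface.query(T.apply(pts))
        mse = float(np.mean(dist ** 2))
        if mse <= 1e-7 or prev - mse < 1e-10:
            break
        prev = mse
        T, _ = kabsch(pts, near)
    final = icp(src_pts, dst_mesh.vertices, init=T, mse_tol=mse_tol,
                max_iter=max_iter, seed=seed)
    return ICPResult(transform=final.transform, final_mse=final.final_mse,
                     iterations=first.iterations + it2 + final.iterations,
                     converged_by=final.converged_by,
                     converged=final.converged_by != "max_iter")


class MeshDistance:
    """Reusable point-to-surface distance queries against one mesh.

    Candidate faces are found through a KD-tree over face centroids (the k
    nearest per query point), then resolved by exact point-triangle
    projection. Exact when the true nearest face is among the candidates,
    which holds for queries within a few edge lengths of the surface.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 16):
        self.triangles = np.asarray(mesh.triangles, float)
        self.k = min(k, len(self.triangles))
        self._tree = cKDTree(self.triangles.mean(axis=1))

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest surface points and unsigned distances (mm)."""
        pts = np.atleast_2d(np.asarray(points, float))
        _, idx = self._tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        n, kk = idx.shape
        cand = self.triangles[idx.ravel()]
        rep = np.repeat(pts, kk, axis=0)
        near = trimesh.triangles.closest_point(cand, rep)
        d = np.linalg.norm(near - rep, axis=1).reshape(n, kk)
        best = np.argmin(d, axis=1)
        return near.reshape(n, kk, 3)[np.arange(n), best], d[np.arange(n), best]


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                          k: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """One-shot convenience wrapper around :class:`MeshDistance`."""
    return MeshDistance(mesh, k=k).query(points)


# ---------------------------------------------------------------------------
# anatomical frame
# ---------------------------------------------------------------------------

def build_frame(landmarks, side: str = "right") -> AnatomicalFrame:
    """Measurement frame from pelvic landmarks.

    The APP is the plane through both anterior superior iliac spines and the
    pubic midpoint. x runs through the bilateral femoral head centres
    (projected into the APP) toward the contralateral side; z is the in-APP
    cephalad direction perpendicular to x; y = z × x. Models should be in
    right-hip convention (see ``raoplan.model.ensure_right``) so that y points
    anterior.
    """
    a_l = np.asarray(landmarks.ASIS_left, float)
    a_r = np.asarray(landmarks.ASIS_right, float)
    pm = 0.5 * (np.asarray(landmarks.pubic_left, float)
                + np.asarray(landmarks.pubic_right, float))
    n = np.cross(a_r - pm, a_l - pm)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DegenerateInputError("APP landmarks are collinear")
    n /= nn
    hc = {"right": np.asarray(landmarks.head_center_right, float),
          "left": np.asarray(landmarks.head_center_left, float)}
    if side not in hc:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    origin = hc[side]
    contra = hc["left" if side == "right" else "right"]
    # orient the APP normal anterior: the head centres sit posterior to the APP
    head_mid = 0.5 * (hc["left"] + hc["right"])
    if n @ (head_mid - pm) > 0:
        n = -n
    x = contra - origin
    x = x - (x @ n) * n
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateInputError("head-centre line is perpendicular to the APP")
    x /= nx
    up = 0.5 * (a_l + a_r) - pm
    z = up - (up @ n) * n - (up @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise DegenerateInputError("cephalad direction is undetermined")
    z /= nz
    y = np.cross(z, x)
    return AnatomicalFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# plane sectioning
# ---------------------------------------------------------------------------

def plane_section(mesh: trimesh.Trimesh, plane_point, plane_normal) -> list[np.ndarray]:
    """Ordered intersection polylines of a triangulated surface with a plane.

    Returns a (possibly empty) list of (n, 3) vertex arrays, each an ordered
    polyline; closed contours repeat their first vertex at the end.
    """
    normal = np.asarray(plane_normal, float)
    nn = np.linalg.norm(normal)
    if not np.isclose(nn, 1.0, atol=1e-6):
        normal = normal / nn
    section = mesh.section(plane_origin=np.asarray(plane_point, float),
                           plane_normal=normal)
    if section is None:
        return []
    verts = np.asarray(section.vertices, float)
    return [verts[np.asarray(e.points)] for e in section.entities]
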