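"""Domain containers: hip surface models and named anatomical landmarks.

A :class:`HipModel` bundles the triangulated hemipelvis and femoral-head
surfaces (mm) with a :class:`LandmarkSet` and a side flag. The internal
measurement convention is right-hip: left models are mirrored on entry
(:func:`ensure_right`) so a single clock convention (x mediolateral toward
the contralateral hip, y anterior, z cephalad) serves everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from typing import Literal

import numpy as np
import trimesh

from .errors import DegenerateInputError
from .geometry import RigidTransform

__all__ = ["LandmarkSet", "HipModel", "mirror_model", "ensure_right"]

_POINT_FIELDS = ("ASIS_left", "ASIS_right", "pubic_left", "pubic_right",
                 "head_center_left", "head_center_right", "koehler_a", "koehler_b")


@dataclass(frozen=True)
class LandmarkSet:
    """Named pelvic landmarks (mm).

    ``koehler_a``/``koehler_b`` span the ilioischial (Koehler) line proxy on
    the medial wall; ``rim_polyline`` is an ordered closed loop of points on
    the acetabular rim (first point not repeated).
    """

    ASIS_left: np.ndarray
    ASIS_right: np.ndarray
    pubic_left: np.ndarray
    pubic_right: np.ndarray
    head_center_left: np.ndarray
    head_center_right: np.ndarray
    koehler_a: np.ndarray
    koehler_b: np.ndarray
    rim_polyline: np.ndarray

    def __post_init__(self):
        for name in _POINT_FIELDS:
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        rim = np.asarray(self.rim_polyline, float)
        if rim.ndim != 2 or rim.shape[1] != 3 or len(rim) < 3:
            raise DegenerateInputError("rim_polyline must be an (n>=3, 3) loop")
        object.__setattr__(self, "rim_polyline", rim)
        if np.allclose(self.head_center_left, self.head_center_right):
            raise DegenerateInputError("bilateral head centers coincide")
        ab = self.ASIS_left - self.ASIS_right
        pm = 0.5 * (self.pubic_left + self.pubic_right)
        ap = self.ASIS_right - pm
        if np.linalg.norm(np.cross(ab, ap)) < 1e-9:
            raise DegenerateInputError("APP landmarks are collinear")

    def points(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _POINT_FIELDS}

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        """Apply a rigid transform to every landmark, rim included."""
        kw = {name: T.apply(getattr(self, name)) for name in _POINT_FIELDS}
        return LandmarkSet(rim_polyline=T.apply(self.rim_polyline), **kw)

    def replace(self, **kw) -> "LandmarkSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class HipModel:
    pelvis_mesh: trimesh.Trimesh
    head_mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    side: Literal["left", "right"] = "right"

    def __post_init__(self):
        for mesh in (self.pelvis_mesh, self.head_mesh):
            if not np.all(np.isfinite(mesh.vertices)):
                raise ValueError("mesh contains non-finite coordinates")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def operative_head_center(self) -> np.ndarray:
        return (self.landmarks.head_center_right if self.side == "right"
                else self.landmarks.head_center_left)

    def transformed(self, T: RigidTransform) -> "HipModel":
        return HipModel(pelvis_mesh=T.transform_mesh(self.pelvis_mesh),
                        head_mesh=T.transform_mesh(self.head_mesh),
                        landmarks=self.landmarks.transformed(T),
                        side=self.side)


def _reflect(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    d = (np.atleast_2d(points) - origin) @ normal
    out = np.atleast_2d(points) - 2.0 * d[:, None] * normal
    return out.reshape(np.shape(points))


def mirror_model(model: HipModel) -> HipModel:
    """Reflect a model across the mid-sagittal plane and swap its side.

    The mirror plane passes through the midpoint of the two ASIS points with
    normal along the inter-ASIS line. Face windings are reversed so outward
    normals survive the reflection. Applying the function twice is exact.
    """
    lm = model.landmarks
    n = lm.ASIS_left - lm.ASIS_right
    n = n / np.linalg.norm(n)
    m = 0.5 * (lm.ASIS_left + lm.ASIS_right)

    def refl_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=_reflect(mesh.vertices, m, n),
                               faces=mesh.faces[:, ::-1].copy(), process=False)

    new_lm = LandmarkSet(
        ASIS_left=_reflect(lm.ASIS_right, m, n),
        ASIS_right=_reflect(lm.ASIS_left, m, n),
        pubic_left=_reflect(lm.pubic_right, m, n),
        pubic_right=_reflect(lm.pubic_left, m, n),
        head_center_left=_reflect(lm.head_center_right, m, n),
        head_center_right=_reflect(lm.head_center_left, m, n),
        koehler_a=_reflect(lm.koehler_a, m, n),
        koehler_b=_reflect(lm.koehler_b, m, n),
        rim_polyline=_reflect(lm.rim_polyline, m, n),
    )
    return HipModel(pelvis_mesh=refl_mesh(model.pelvis_mesh),
                    head_mesh=refl_mesh(model.head_mesh),
                    landmarks=new_lm,
                    side="left" if model.side == "right" else "right")


def ensure_right(model: HipModel) -> HipModel:
    """Return the model in right-hip convention, mirroring if necessary."""
    return model if model.side == "right" else mirror_model(model)
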