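"""Serialization: STL meshes, JSON landmarks/plans, CSV profiles.

All JSON documents carry a ``schema_version`` field. Meshes are written as
ASCII STL by default (portable and diff-friendly); pass ``binary=True`` for
compact files. Missing profile values are encoded as empty cells, never as
zeros.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import ConfigurationError
from .geometry import RigidTransform, Sphere
from .measure import ASAProfile, DeltaProfile
from .model import HipModel, LandmarkSet
from .planner import FiducialSet, OsteotomyPlan, PlanTargets

SCHEMA_VERSION = 1

__all__ = [
    "save_mesh", "load_mesh",
    "save_landmarks", "load_landmarks",
    "save_hip_model", "load_hip_model",
    "save_plan", "load_plan",
    "profile_to_csv", "profile_from_csv",
]


def save_mesh(mesh: trimesh.Trimesh, path: str | Path, binary: bool = False) -> Path:
    path = Path(path)
    data = trimesh.exchange.stl.export_stl(mesh) if binary else \
        trimesh.exchange.stl.export_stl_ascii(mesh).encode()
    path.write_bytes(data)
    return path


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    # STL stores an unindexed triangle soup; merge coincident vertices so
    # connectivity-based operations (osteotomy components, sections) work
    mesh = trimesh.load_mesh(str(path), process=True)
    return trimesh.Trimesh(vertices=np.asarray(mesh.vertices, float),
                           faces=np.asarray(mesh.faces, int), process=False)


def save_landmarks(landmarks: LandmarkSet, path: str | Path,
                   side: str = "right") -> Path:
    doc = {"schema_version": SCHEMA_VERSION, "side": side,
           "points": {k: v.tolist() for k, v in landmarks.points().items()},
           "rim_polyline": landmarks.rim_polyline.tolist()}
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_landmarks(path: str | Path) -> tuple[LandmarkSet, str]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported landmark schema in {path}")
    lm = LandmarkSet(rim_polyline=np.asarray(doc["rim_polyline"], float),
                     **{k: np.asarray(v, float) for k, v in doc["points"].items()})
    return lm, doc.get("side", "right")


def save_hip_model(model: HipModel, out_dir: str | Path,
                   binary: bool = False) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mesh(model.pelvis_mesh, out / "pelvis.stl", binary=binary)
    save_mesh(model.head_mesh, out / "head.stl", binary=binary)
    save_landmarks(model.landmarks, out / "landmarks.json", side=model.side)
    return out


def load_hip_model(model_dir: str | Path) -> HipModel:
    d = Path(model_dir)
    lm, side = load_landmarks(d / "landmarks.json")
    return HipModel(pelvis_mesh=load_mesh(d / "pelvis.stl"),
                    head_mesh=load_mesh(d / "head.stl"),
                    landmarks=lm, side=side)


def _transform_to_doc(T: RigidTransform) -> dict:
    return {"rotation": T.rotation.tolist(), "translation": T.translation.tolist()}


def _transform_from_doc(doc: dict) -> RigidTransform:
    return RigidTransform(np.asarray(doc["rotation"], float),
                          np.asarray(doc["translation"], float))


def save_plan(plan: OsteotomyPlan, out_dir: str | Path,
              binary: bool = False) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mesh(plan.fragment_mesh, out / "fragment.stl", binary=binary)
    save_mesh(plan.remainder_mesh, out / "remainder.stl", binary=binary)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "osteotomy_sphere": {"center": plan.osteotomy_sphere.center.tolist(),
                             "radius": plan.osteotomy_sphere.radius},
        "reorientation": _transform_to_doc(plan.reorientation),
        "targets": asdict(plan.targets),
        "achieved": {k: float(v) for k, v in plan.achieved.items()},
        "head_center": plan.head_center.tolist(),
        "source_vertex_count": plan.source_vertex_count,
    }
    if plan.fiducials is not None:
        fid = plan.fiducials
        doc["fiducials"] = {
            "notch_diameter_mm": fid.notch_diameter_mm,
            "arc_span_deg": fid.arc_span_deg,
            "pre": {lab: p.tolist() for lab, p in zip(fid.pre_labels,
                                                      fid.pre_points)},
            "relocated": None if fid.relocated_points is None else
            {lab: p.tolist() for lab, p in zip(fid.relocated_labels,
                                               fid.relocated_points)},
        }
    (out / "plan.json").write_text(json.dumps(doc, indent=2))
    return out


def load_plan(plan_dir: str | Path) -> OsteotomyPlan:
    d = Path(plan_dir)
    doc = json.loads((d / "plan.json").read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported plan schema in {plan_dir}")
    fiducials = None
    if "fiducials" in doc:
        f = doc["fiducials"]
        rel = f.get("relocated")
        fiducials = FiducialSet(
            pre_points=np.array([f["pre"][lab] for lab in sorted(f["pre"])]),
            relocated_points=None if rel is None else
            np.array([rel[lab] for lab in sorted(rel)]),
            notch_diameter_mm=f["notch_diameter_mm"],
            arc_span_deg=f["arc_span_deg"])
    t = doc["targets"]
    return OsteotomyPlan(
        osteotomy_sphere=Sphere(np.asarray(doc["osteotomy_sphere"]["center"]),
                                doc["osteotomy_sphere"]["radius"]),
        fragment_mesh=load_mesh(d / "fragment.stl"),
        remainder_mesh=load_mesh(d / "remainder.stl"),
        reorientation=_transform_from_doc(doc["reorientation"]),
        targets=PlanTargets(target_aro_deg=t["target_aro_deg"],
                            target_anterior_ce_deg=tuple(t["target_anterior_ce_deg"]),
                            target_koehler_mm=tuple(t["target_koehler_mm"])),
        fiducials=fiducials,
        achieved=doc["achieved"],
        head_center=np.asarray(doc["head_center"], float),
        source_vertex_count=doc["source_vertex_count"])


def profile_to_csv(profile: ASAProfile | DeltaProfile, path: str | Path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False, na_rep="")
    return path


def profile_from_csv(path: str | Path) -> ASAProfile | DeltaProfile:
    df = pd.read_csv(path)
    if "delta_deg" in df.columns:
        return DeltaProfile(positions=tuple(df["position"].astype(str)),
                            values_deg=df["delta_deg"].to_numpy(float))
    source = str(df["source"].iloc[0]) if "source" in df.columns else "preoperative"
    return ASAProfile(positions=tuple(df["position"].astype(str)),
                      values_deg=df["value_deg"].to_numpy(float), source=source)
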