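"""End-to-end simulation: plan, operate (with error), image, register, measure.

One simulated case mirrors the clinical evaluation loop: a dysplastic
phantom is planned (virtual spherical osteotomy + reorientation solve), an
intraoperative confirmation method accepts a placement drawn from an error
model, a postoperative model is synthesized at the accepted pose, the
planning model is registered onto it with ICP, and both are measured on the
same clock face to yield the per-position ΔASA. Cohorts of such cases are
compared per position with the unpaired t test.

Two confirmation methods are simulated. The surface-touch check ("previous")
accepts when digitized points on the lateral fragment surface lie close to
the planned surface — a test that is blind to rotations that slide the
spherical lateral cortex over itself. The four-fiducial check accepts only
when each digitized rim notch lies close to its own relocated counterpart
(#1->#5 ... #4->#8), which constrains the full pose.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import trimesh

from . import __version__ as _pkg_version
from .errors import ConfigurationError, SimulationError
from .geometry import (MeshDistance, RigidTransform, build_frame,
                       centroid_align, fit_sphere, icp, kabsch, robust_icp)
from .measure import (ASAProfile, DeltaProfile, asa_profile, build_clock_face,
                      delta_profile)
from .model import HipModel, ensure_right
from .phantom import (ErrorModel, PhantomParams, make_hip_phantom,
                      make_postoperative_model, simulate_digitization)
from .planner import OsteotomyPlan, PlanTargets, plan_case
from .stats import GroupComparison, compare_groups

__all__ = [
    "RegistrationResult", "CaseResult", "MethodDraw",
    "build_planning_model", "register_models",
    "simulate_previous_method", "simulate_fiducial_method",
    "fiducial_distances",
    "draw_misplacement", "run_case", "run_cohort",
    "run_method_comparison", "replicate_significance", "make_report",
    "reproduce_from_manifest",
]

MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    final_mse: float
    iterations: int
    converged_by: str

    @property
    def converged(self) -> bool:
        return self.converged_by != "max_iter"


def build_planning_model(model: HipModel, plan: OsteotomyPlan) -> HipModel:
    """The planning model: remainder plus the reoriented fragment, with the
    femoral head and operative-side landmarks carried along."""
    m = ensure_right(model)
    T = plan.reorientation
    pelvis = trimesh.util.concatenate(
        trimesh.Trimesh(vertices=plan.remainder_mesh.vertices.copy(),
                        faces=plan.remainder_mesh.faces.copy(), process=False),
        T.transform_mesh(plan.fragment_mesh))
    lm = m.landmarks.replace(
        head_center_right=T.apply(m.landmarks.head_center_right),
        rim_polyline=T.apply(m.landmarks.rim_polyline))
    return HipModel(pelvis_mesh=pelvis, head_mesh=T.transform_mesh(m.head_mesh),
                    landmarks=lm, side=m.side)


_PELVIC_LANDMARKS = ("ASIS_left", "ASIS_right", "pubic_left", "pubic_right",
                     "koehler_a", "koehler_b")


def _landmark_init(plan_model: HipModel, post_model: HipModel) -> RigidTransform:
    """Coarse pose from paired remainder-fixed landmarks (ASIS, pubis,
    Koehler proxy, contralateral head centre) — the digitized points a
    navigation workflow pairs before surface refinement."""
    contra = ("head_center_left" if plan_model.side == "right"
              else "head_center_right")
    names = _PELVIC_LANDMARKS + (contra,)
    src = np.array([getattr(plan_model.landmarks, n) for n in names])
    dst = np.array([getattr(post_model.landmarks, n) for n in names])
    T, _ = kabsch(src, dst)
    return T


def register_models(plan_model: HipModel, post_model: HipModel,
                    region: Literal["full", "non_fragment"] = "non_fragment",
                    plan: OsteotomyPlan | None = None,
                    init: Literal["landmarks", "centroid"] | RigidTransform = "landmarks",
                    mse_tol: float = 1.0e-5, max_iter: int = 200,
                    seed: int = 0) -> RegistrationResult:
    """ICP of the planning model onto the postoperative model.

    With ``region="non_fragment"`` (default) only the iliac remainder drives
    the registration, so fragment misplacement cannot bias the pelvis
    alignment; ``region="full"`` uses the whole pelvis surface, as in a
    fidelity run. ``init`` selects the coarse alignment: paired pelvic
    landmarks (default), centroid alignment, or an explicit transform; with
    centroid initialisation the surface-projection escape stage of
    :func:`raoplan.geometry.robust_icp` guards against vertex-lattice
    locking. The result maps planning coordinates into the postoperative
    scan frame.
    """
    if region == "non_fragment":
        if plan is None:
            raise ConfigurationError("region='non_fragment' needs the plan")
        src = plan.remainder_mesh.vertices
    elif region == "full":
        src = plan_model.pelvis_mesh.vertices
    else:
        raise ConfigurationError(f"unknown registration region {region!r}")
    dst_mesh = post_model.pelvis_mesh
    if isinstance(init, RigidTransform):
        res = icp(src, dst_mesh.vertices, init=init, mse_tol=mse_tol,
                  max_iter=max_iter, seed=seed)
    elif init == "landmarks":
        T0 = _landmark_init(plan_model, post_model)
        res = icp(src, dst_mesh.vertices, init=T0, mse_tol=mse_tol,
                  max_iter=max_iter, seed=seed)
    elif init == "centroid":
        res = robust_icp(src, dst_mesh,
                         init=centroid_align(src, dst_mesh.vertices),
                         mse_tol=mse_tol, max_iter=max_iter, seed=seed)
    else:
        raise ConfigurationError(f"unknown init {init!r}")
    return RegistrationResult(transform=res.transform, final_mse=res.final_mse,
                              iterations=res.iterations,
                              converged_by=res.converged_by)


# ---------------------------------------------------------------------------
# intraoperative confirmation simulators
# ---------------------------------------------------------------------------

def draw_misplacement(error_model: ErrorModel, center: np.ndarray,
                      rng: np.random.Generator) -> RigidTransform:
    """One attempted placement: per-axis normal rotation (degrees) about the
    planned head centre plus per-axis normal translation (mm)."""
    rotvec = rng.normal(0.0, error_model.rot_sd_deg, size=3)
    trans = rng.normal(0.0, error_model.trans_sd_mm, size=3)
    return RigidTransform.from_rotvec(rotvec, center=center, translation=trans)


@dataclass(frozen=True)
class MethodDraw:
    """Accepted placement from a confirmation simulator."""

    misplacement: RigidTransform
    attempts: int
    info: dict = field(default_factory=dict)


def _lateral_probe_points(planned_fragment: trimesh.Trimesh, center: np.ndarray,
                          frame, azimuths=(-40.0, -20.0, 0.0, 20.0, 40.0),
                          polar_deg: float = 65.0) -> np.ndarray:
    """Material points on the outer (lateral) fragment surface: for each
    superolateral direction, the farthest fragment vertex within a narrow
    cone — the spot a surgeon would reach with the pointer."""
    verts = np.asarray(planned_fragment.vertices, float)
    v = verts - center
    r = np.linalg.norm(v, axis=1)
    u = v / r[:, None]
    out = []
    for az in azimuths:
        a = np.radians(az)
        p = np.radians(polar_deg)
        d = (np.cos(p) * frame.x_axis
             + np.sin(p) * (np.cos(a) * frame.z_axis + np.sin(a) * frame.y_axis))
        for cone_deg in (6.0, 10.0, 16.0, 30.0):
            sel = np.flatnonzero(u @ d >= np.cos(np.radians(cone_deg)))
            if len(sel):
                out.append(verts[sel[np.argmax(r[sel])]])
                break
        else:
            raise SimulationError("no lateral surface in the probe direction")
    return np.array(out)


def simulate_previous_method(model: HipModel, plan: OsteotomyPlan,
                             error_model: ErrorModel, seed: int,
                             n_points: int = 5,
                             max_attempts: int = MAX_ATTEMPTS) -> MethodDraw:
    """Surface-touch confirmation (rejection sampler).

    Placements are drawn from the error model until every one of ``n_points``
    digitized points on the lateral surface of the (misplaced) fragment lies
    within the acceptance tolerance of the planned fragment surface. Because
    the lateral cortex is nearly spherical about the head centre, rotations
    largely slide the surface over itself and pass the check.
    """
    if error_model.method != "previous":
        raise ConfigurationError("error model is not for the previous method")
    m = ensure_right(model)
    frame = build_frame(m.landmarks, m.side)
    planned_frag = plan.reorientation.transform_mesh(plan.fragment_mesh)
    center = plan.planned_head_center
    azimuths = np.linspace(-40.0, 40.0, n_points)
    probes = _lateral_probe_points(planned_frag, center, frame, azimuths)
    surface = MeshDistance(planned_frag)
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        M = draw_misplacement(error_model, center, rng)
        touched = M.apply(probes)
        digitized = simulate_digitization(touched, error_model.digitization_sd_mm,
                                          int(rng.integers(2 ** 31 - 1)))
        _, dist = surface.query(digitized)
        if np.all(dist <= error_model.acceptance_tol_mm):
            return MethodDraw(misplacement=M, attempts=attempt,
                              info={"max_surface_distance_mm": float(dist.max())})
    raise SimulationError(
        f"no placement accepted in {max_attempts} attempts; the acceptance "
        "tolerance is inconsistent with the error model")


def fiducial_distances(plan: OsteotomyPlan,
                       misplacement: RigidTransform) -> np.ndarray:
    """Distance of each (noise-free) fiducial from its relocated counterpart
    under a candidate placement — the quantity the all-four rule thresholds."""
    if plan.fiducials is None or plan.fiducials.relocated_points is None:
        raise ConfigurationError("plan carries no relocated fiducials")
    rel = plan.fiducials.relocated_points
    return np.linalg.norm(misplacement.apply(rel) - rel, axis=1)


def simulate_fiducial_method(model: HipModel, plan: OsteotomyPlan,
                             error_model: ErrorModel, seed: int,
                             max_attempts: int = MAX_ATTEMPTS) -> MethodDraw:
    """Four-fiducial confirmation (rejection sampler).

    A placement is accepted only when each digitized fiducial lies within
    the acceptance tolerance of its own relocated counterpart (#1->#5 ...),
    i.e. all four must match. The pose residual of the accepted draw
    (Kabsch of digitized onto relocated points) is reported.
    """
    if error_model.method != "fiducial":
        raise ConfigurationError("error model is not for the fiducial method")
    if plan.fiducials is None or plan.fiducials.relocated_points is None:
        raise ConfigurationError("plan carries no relocated fiducials")
    relocated = plan.fiducials.relocated_points
    center = plan.planned_head_center
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        M = draw_misplacement(error_model, center, rng)
        actual = M.apply(relocated)
        digitized = simulate_digitization(actual, error_model.digitization_sd_mm,
                                          int(rng.integers(2 ** 31 - 1)))
        dist = np.linalg.norm(digitized - relocated, axis=1)
        if np.all(dist <= error_model.acceptance_tol_mm):
            pose, _ = kabsch(relocated, digitized)
            return MethodDraw(misplacement=M, attempts=attempt,
                              info={"max_fiducial_distance_mm": float(dist.max()),
                                    "pose_rotation_deg": pose.rotation_angle_deg(),
                                    "pose_translation_mm": float(
                                        np.linalg.norm(pose.translation))})
    raise SimulationError(
        f"no placement accepted in {max_attempts} attempts; the acceptance "
        "tolerance is inconsistent with the error model")


# ---------------------------------------------------------------------------
# cases and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseResult:
    case_id: str
    method: str
    true_misplacement: RigidTransform
    delta_profile: DeltaProfile
    attempts_until_accept: int
    registration: RegistrationResult
    plan_profile: ASAProfile
    post_profile: ASAProfile

    def __post_init__(self):
        if self.attempts_until_accept < 1:
            raise ConfigurationError("attempts_until_accept must be >= 1")


def run_case(phantom_params: PhantomParams | None = None,
             plan_targets: PlanTargets | None = None,
             error_model: ErrorModel | None = None,
             seed: int = 0,
             surface_noise_mm: float = 0.2,
             scanner_pose: RigidTransform | None = None,
             region: str = "non_fragment",
             model: HipModel | None = None,
             plan: OsteotomyPlan | None = None,
             case_id: str | None = None) -> CaseResult:
    """One simulated joint, fully seeded.

    phantom -> plan -> confirmation-method draw -> postoperative model ->
    ICP registration -> clock-face profiles -> ΔASA. A prebuilt ``model`` and
    ``plan`` may be passed to amortize planning across a cohort (the phantom
    and plan are deterministic given their parameters).
    """
    error_model = error_model or ErrorModel.fiducial_default()
    if model is None:
        model = make_hip_phantom(phantom_params or PhantomParams())
    model = ensure_right(model)
    if plan is None:
        plan = plan_case(model, plan_targets)
    rng = np.random.default_rng(seed)
    sim_seed, post_seed, icp_seed = (int(s) for s in rng.integers(2 ** 31 - 1, size=3))

    if error_model.method == "previous":
        draw = simulate_previous_method(model, plan, error_model, sim_seed)
    else:
        draw = simulate_fiducial_method(model, plan, error_model, sim_seed)

    post = make_postoperative_model(model, plan, draw.misplacement,
                                    surface_noise_mm=surface_noise_mm,
                                    seed=post_seed, scanner_pose=scanner_pose)
    planning = build_planning_model(model, plan)
    reg = register_models(planning, post, region=region, plan=plan,
                          seed=icp_seed)
    planning_in_post = planning.transformed(reg.transform)

    frame = build_frame(post.landmarks, post.side)
    face = build_clock_face(frame)
    plan_prof = asa_profile(planning_in_post, face,
                            head_center=reg.transform.apply(plan.planned_head_center),
                            source="planning")
    post_prof = asa_profile(post, face, source="postoperative")
    delta = delta_profile(post_prof, plan_prof)
    return CaseResult(case_id=case_id or f"{error_model.method}-{seed}",
                      method=error_model.method,
                      true_misplacement=draw.misplacement,
                      delta_profile=delta,
                      attempts_until_accept=draw.attempts,
                      registration=reg,
                      plan_profile=plan_prof, post_profile=post_prof)


def run_cohort(n_cases: int, error_model: ErrorModel,
               phantom_params: PhantomParams | None = None,
               plan_targets: PlanTargets | None = None,
               seed: int = 0, surface_noise_mm: float = 0.2,
               region: str = "non_fragment",
               model: HipModel | None = None,
               plan: OsteotomyPlan | None = None) -> list[CaseResult]:
    """A cohort of simulated joints sharing one phantom and one plan but
    independent placement errors, noise and scanner poses."""
    if model is None:
        model = make_hip_phantom(phantom_params or PhantomParams())
    if plan is None:
        plan = plan_case(model, plan_targets)
    case_seeds = np.random.default_rng(seed).integers(2 ** 31 - 1, size=n_cases)
    return [run_case(error_model=error_model, seed=int(s),
                     surface_noise_mm=surface_noise_mm, region=region,
                     model=model, plan=plan,
                     case_id=f"{error_model.method}-{i:03d}")
            for i, s in enumerate(case_seeds)]


@dataclass(frozen=True)
class ComparisonRun:
    cohort_previous: list[CaseResult]
    cohort_fiducial: list[CaseResult]
    comparison: GroupComparison
    config: dict


def run_method_comparison(n_per_group: int = 20, seed: int = 0,
                          error_previous: ErrorModel | None = None,
                          error_fiducial: ErrorModel | None = None,
                          phantom_params: PhantomParams | None = None,
                          plan_targets: PlanTargets | None = None,
                          surface_noise_mm: float = 0.2,
                          signed: bool = False,
                          model: HipModel | None = None,
                          plan: OsteotomyPlan | None = None) -> ComparisonRun:
    """Simulate both confirmation-method cohorts and compare them per
    position, emulating the two-arm accuracy study design."""
    error_previous = error_previous or ErrorModel.previous_default()
    error_fiducial = error_fiducial or ErrorModel.fiducial_default()
    phantom_params = phantom_params or PhantomParams()
    plan_targets = plan_targets or PlanTargets()
    if model is None:
        model = make_hip_phantom(phantom_params)
    if plan is None:
        plan = plan_case(model, plan_targets)
    rng = np.random.default_rng(seed)
    seed_prev, seed_fid = (int(s) for s in rng.integers(2 ** 31 - 1, size=2))
    prev = run_cohort(n_per_group, error_previous, phantom_params, plan_targets,
                      seed=seed_prev, surface_noise_mm=surface_noise_mm,
                      model=model, plan=plan)
    fid = run_cohort(n_per_group, error_fiducial, phantom_params, plan_targets,
                     seed=seed_fid, surface_noise_mm=surface_noise_mm,
                     model=model, plan=plan)
    comparison = compare_groups(prev, fid, signed=signed)
    config = {
        "schema_version": 1,
        "seed": seed,
        "n_per_group": n_per_group,
        "surface_noise_mm": surface_noise_mm,
        "signed": signed,
        "error_previous": asdict(error_previous),
        "error_fiducial": asdict(error_fiducial),
        "phantom_params": asdict(phantom_params),
        "plan_targets": asdict(plan_targets),
        "versions": {"raoplan": _pkg_version, "numpy": np.__version__},
    }
    return ComparisonRun(cohort_previous=prev, cohort_fiducial=fid,
                         comparison=comparison, config=config)


def replicate_significance(n_replicates: int = 50, n_per_group: int = 20,
                           seed: int = 0, position: str = "12:00",
                           alpha: float = 0.05, **kwargs) -> dict:
    """Replicate the two-cohort comparison and summarise the headline test.

    Runs ``n_replicates`` independent cohort pairs (sharing one phantom and
    plan, so only the simulated errors differ) and reports how often the
    fiducial group's mean |ΔASA| at ``position`` is smaller and how often
    the unpaired t test there is significant at ``alpha``.
    """
    model = make_hip_phantom(kwargs.get("phantom_params") or PhantomParams())
    plan = plan_case(model, kwargs.get("plan_targets"))
    rep_seeds = np.random.default_rng(seed).integers(2 ** 31 - 1,
                                                     size=n_replicates)
    smaller = 0
    significant = 0
    both = 0
    p_values = []
    for s in rep_seeds:
        run = run_method_comparison(n_per_group=n_per_group, seed=int(s),
                                    model=model, plan=plan, **kwargs)
        comp = run.comparison
        j = comp.positions.index(position)
        is_smaller = comp.mean_b[j] < comp.mean_a[j]
        is_sig = comp.p_value[j] < alpha
        smaller += is_smaller
        significant += is_sig
        both += is_smaller and is_sig
        p_values.append(float(comp.p_value[j]))
    return {
        "position": position,
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
        "fraction_fiducial_smaller": smaller / n_replicates,
        "fraction_significant": significant / n_replicates,
        "fraction_smaller_and_significant": both / n_replicates,
        "median_p": float(np.median(p_values)),
    }


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _profile_summary(cohort: Sequence[CaseResult], attr: str) -> np.ndarray:
    return np.mean([getattr(c, attr).values_deg for c in cohort], axis=0)


def make_report(run: ComparisonRun, out_dir: str | Path,
                boxplot: bool = False) -> list[Path]:
    """Write the per-position comparison CSV, the run manifest (JSON) and an
    optional |ΔASA| box plot; returns the written paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create report directory {out}: {exc}") from exc

    comp = run.comparison
    df = comp.to_frame()
    df.insert(1, "mean_plan_asa_previous",
              _profile_summary(run.cohort_previous, "plan_profile"))
    df.insert(2, "mean_post_asa_previous",
              _profile_summary(run.cohort_previous, "post_profile"))
    df.insert(3, "mean_plan_asa_fiducial",
              _profile_summary(run.cohort_fiducial, "plan_profile"))
    df.insert(4, "mean_post_asa_fiducial",
              _profile_summary(run.cohort_fiducial, "post_profile"))
    csv_path = out / "comparison.csv"
    df.to_csv(csv_path, index=False, float_format="%.4f")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(run.config, indent=2, sort_keys=True))

    paths = [csv_path, manifest_path]
    if boxplot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(10, 4))
        pos = np.arange(len(comp.positions))
        prev = np.abs([c.delta_profile.values_deg for c in run.cohort_previous])
        fid = np.abs([c.delta_profile.values_deg for c in run.cohort_fiducial])
        ax.boxplot([prev[:, j] for j in pos], positions=pos - 0.18,
                   widths=0.3, patch_artist=True,
                   boxprops=dict(facecolor="#d95f02aa"))
        ax.boxplot([fid[:, j] for j in pos], positions=pos + 0.18,
                   widths=0.3, patch_artist=True,
                   boxprops=dict(facecolor="#1b9e77aa"))
        ax.set_xticks(pos, comp.positions, rotation=45)
        ax.set_ylabel("|ΔASA| (deg)")
        ax.set_title("previous (orange) vs fiducial (green) confirmation")
        fig.tight_layout()
        png_path = out / "delta_asa_boxplot.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths.append(png_path)
    return paths


def reproduce_from_manifest(manifest_path: str | Path,
                            out_dir: str | Path) -> list[Path]:
    """Re-run a reported comparison from its manifest; identical manifests
    reproduce identical CSVs."""
    cfg = json.loads(Path(manifest_path).read_text())
    run = run_method_comparison(
        n_per_group=cfg["n_per_group"], seed=cfg["seed"],
        error_previous=ErrorModel(**cfg["error_previous"]),
        error_fiducial=ErrorModel(**cfg["error_fiducial"]),
        phantom_params=PhantomParams(**cfg["phantom_params"]),
        plan_targets=PlanTargets(
            target_aro_deg=cfg["plan_targets"]["target_aro_deg"],
            target_anterior_ce_deg=tuple(cfg["plan_targets"]["target_anterior_ce_deg"]),
            target_koehler_mm=tuple(cfg["plan_targets"]["target_koehler_mm"])),
        surface_noise_mm=cfg["surface_noise_mm"], signed=cfg["signed"])
    return make_report(run, out_dir)
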