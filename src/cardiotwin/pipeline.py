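"""End-to-end orchestration: bundles in, cohort outputs out.

Each participant runs through frame selection, contour/landmark extraction,
surface fitting at ED and ES, RV epicardium generation, volumetric meshing
with coordinates and fibers, and phenotype derivation. Failures are
recorded per participant with the failing stage and never abort the cohort.
The cohort stage then applies the IQR quality-control rule, bins the
survivors demographically and builds representative meshes.

Runs are deterministic under a fixed seed and configuration; the manifest
carries content hashes so two identical runs produce identical manifests
and a completed run directory can be resumed without recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cohort as co
from . import contours as ct
from . import core_io as cio
from . import frames as fr
from . import phenotypes as phe
from . import qc as qcmod
from . import surface as sf
from . import uvc as uv
from . import volmesh as vm
from .core_io import CineView, StudyBundle


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's stated constants."""

    ed_policy: str = "first"  # or "maxlv"
    rv_wall_thickness: float = 3.0  # mm
    alpha_endo: float = 60.0  # degrees
    alpha_epi: float = -60.0
    beta_endo: float = -65.0
    beta_epi: float = 25.0
    myo_density: float = 1.05  # g/mL
    gpa_tolerance: float = 1e-6
    min_bin_members: int = 3
    n_wall_layers: int = 4
    lid_thickness: float = 2.0  # mm
    fit_schedule: tuple = sf.DEFAULT_SCHEDULE
    correct_misalignment: bool = True
    shift_cap: float = 10.0  # mm
    build_representatives: bool = True
    build_volumetric: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ParticipantResult:
    participant_id: str
    ed_frame: int
    es_frame: int
    surface_ed: object
    surface_es: object
    seg_record: object
    mesh_record: object
    volmesh: object = None
    uvc: object = None
    fibers: object = None


@dataclass
class Failure:
    participant_id: str
    stage: str
    reason: str


@dataclass
class CohortResult:
    participants: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    qc_results: list = field(default_factory=list)
    qc_thresholds: dict = field(default_factory=dict)
    kept_ids: list = field(default_factory=list)
    representatives: dict = field(default_factory=dict)
    bin_manifest: list = field(default_factory=list)
    associations: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=np.float64)
                                      .round(9)).tobytes())
    return h.hexdigest()[:16]


def process_participant(bundle: StudyBundle, template, config: PipelineConfig,
                        with_volumetric: bool = True) -> ParticipantResult:
    """Run one participant through the per-case pipeline stages."""
    issues = cio.validate_bundle(
        bundle, required_views=(CineView.SAX, CineView.LAX2CH,
                                CineView.LAX4CH))
    fatal = [i for i in issues if i.code in ("MISSING_VIEW", "BAD_LABELS")]
    if fatal:
        raise RuntimeError(f"validate: {[str(i) for i in fatal]}")
    pick = fr.pick_frames(bundle, fr.EDPolicy(config.ed_policy))

    fitted = {}
    for frame in (pick.ed_frame, pick.es_frame):
        all_contours, lms = [], {}
        for view in CineView:
            series = bundle.get(view)
            if series is None:
                continue
            cs, lm, _ = ct.extract_view(series, frame)
            all_contours.extend(cs)
            lms[view] = lm
        res = sf.fit_surface_multiscale(
            template, all_contours, lms, schedule=config.fit_schedule,
            correct_slices=config.correct_misalignment,
            shift_cap=config.shift_cap)
        mesh = sf.generate_rv_epicardium(res.mesh,
                                         thickness=config.rv_wall_thickness)
        mesh.provenance["participant"] = bundle.participant_id
        mesh.provenance["frame"] = int(frame)
        fitted[frame] = mesh

    seg_rec = phe.seg_phenotypes(bundle, pick.ed_frame, pick.es_frame)
    mesh_rec = phe.mesh_phenotypes(bundle.participant_id,
                                   fitted[pick.ed_frame],
                                   fitted[pick.es_frame])
    out = ParticipantResult(
        participant_id=bundle.participant_id, ed_frame=pick.ed_frame,
        es_frame=pick.es_frame, surface_ed=fitted[pick.ed_frame],
        surface_es=fitted[pick.es_frame], seg_record=seg_rec,
        mesh_record=mesh_rec)
    if with_volumetric:
        out.volmesh = vm.build_biventricular_mesh(
            out.surface_ed, n_layers=config.n_wall_layers,
            lid_thickness=config.lid_thickness)
        out.uvc = uv.compute_uvc(out.volmesh)
        out.fibers = uv.compute_fibers(
            out.volmesh, out.uvc, alpha_endo=config.alpha_endo,
            alpha_epi=config.alpha_epi, beta_endo=config.beta_endo,
            beta_epi=config.beta_epi)
        out.volmesh.point_data.update(out.uvc.as_point_data())
        out.volmesh.cell_data.update(out.fibers.as_cell_data())
    return out


def run_pipeline(bundles: list, config: PipelineConfig | None = None,
                 template=None, run_dir=None) -> CohortResult:
    """Process a cohort of bundles end to end.

    Per-participant failures are recorded with their stage and the cohort
    continues. If ``run_dir`` is given, per-participant manifests are
    written there and :func:`resume` can skip completed work.
    """
    config = config or PipelineConfig()
    template = template or sf.build_template()
    result = CohortResult()
    demographics = {}
    for bundle in sorted(bundles, key=lambda b: b.participant_id):
        pid = bundle.participant_id
        try:
            pr = process_participant(bundle, template, config,
                                     with_volumetric=config.build_volumetric)
        except Exception as err:  # fault isolation: record, continue
            stage = type(err).__name__
            result.failures.append(Failure(pid, stage, str(err)))
            continue
        result.participants[pid] = pr
        if bundle.demographics is not None:
            demographics[pid] = bundle.demographics

    _cohort_stage(result, demographics, config)
    result.manifest = build_manifest(result, config)
    if run_dir is not None:
        write_run(result, config, run_dir)
    return result


def _cohort_stage(result: CohortResult, demographics: dict,
                  config: PipelineConfig) -> None:
    if not result.participants:
        return
    seg = {p: r.seg_record for p, r in result.participants.items()}
    mesh = {p: r.mesh_record for p, r in result.participants.items()}
    if len(seg) >= 4:
        (result.qc_results, result.kept_ids, result.qc_thresholds,
         _) = qcmod.apply_qc(seg, mesh)
    else:
        result.kept_ids = sorted(seg)
    if config.build_representatives and demographics:
        kept_surfaces = {p: result.participants[p].surface_ed
                         for p in result.kept_ids if p in demographics}
        if kept_surfaces:
            reps, _, manifest = co.build_representative_surfaces(
                kept_surfaces,
                {p: demographics[p] for p in kept_surfaces},
                tolerance=config.gpa_tolerance,
                min_members=config.min_bin_members)
            result.representatives = reps
            result.bin_manifest = manifest
    if demographics:
        recs = [result.participants[p].mesh_record
                for p in result.kept_ids if p in demographics]
        if len(recs) >= 3:
            result.associations = co.cohort_associations(recs, demographics)


def build_manifest(result: CohortResult, config: PipelineConfig) -> dict:
    manifest = {"config_hash": config.hash(), "participants": {},
                "failures": [[f.participant_id, f.stage] for f in result.failures],
                "kept": list(result.kept_ids)}
    for pid, pr in sorted(result.participants.items()):
        entry = {
            "ed": pr.ed_frame, "es": pr.es_frame,
            "surface_ed": _hash_array(pr.surface_ed.vertices),
            "surface_es": _hash_array(pr.surface_es.vertices),
            "phenotypes": _hash_array([pr.seg_record.lvedv, pr.seg_record.lvesv,
                                       pr.seg_record.rvedv, pr.seg_record.lvm,
                                       pr.mesh_record.lvedv, pr.mesh_record.lvesv,
                                       pr.mesh_record.rvedv, pr.mesh_record.lvm]),
        }
        if pr.volmesh is not None:
            entry["volmesh"] = _hash_array(pr.volmesh.nodes,
                                           pr.volmesh.tets.astype(float))
            fiber = (pr.fibers.fiber if pr.fibers is not None
                     else pr.volmesh.cell_data.get("fiber"))
            if fiber is not None:
                entry["fibers"] = _hash_array(fiber)
        manifest["participants"][pid] = entry
    manifest["representatives"] = {
        "_".join(map(str, key)): _hash_array(mesh.vertices)
        for key, mesh in sorted(result.representatives.items())}
    return manifest


def write_run(result: CohortResult, config: PipelineConfig, run_dir) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(config.to_json())
    (run_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True))
    for pid, pr in result.participants.items():
        pdir = run_dir / "participants" / pid
        pdir.mkdir(parents=True, exist_ok=True)
        cio.write_mesh(pr.surface_ed, pdir / "surface_ed.vtk")
        cio.write_mesh(pr.surface_es, pdir / "surface_es.vtk")
        if pr.volmesh is not None:
            cio.write_mesh(pr.volmesh, pdir / "volmesh.vtk")
    for key, mesh in result.representatives.items():
        name = "_".join(map(str, key))
        rdir = run_dir / "representatives"
        rdir.mkdir(parents=True, exist_ok=True)
        cio.write_mesh(mesh, rdir / f"{name}.vtk")


def resume(run_dir, bundles: list, config: PipelineConfig | None = None,
           template=None) -> CohortResult:
    """Re-run a cohort, skipping participants already in the manifest.

    Verifies the stored configuration hash; a changed configuration refuses
    to resume. Completed participants are reloaded from their written
    surfaces rather than recomputed.
    """
    run_dir = Path(run_dir)
    config = config or PipelineConfig()
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    old = json.loads(manifest_path.read_text())
    if old.get("config_hash") != config.hash():
        raise RuntimeError("configuration changed since the recorded run; "
                           "refusing to resume")
    template = template or sf.build_template()
    result = CohortResult()
    demographics = {}
    for bundle in sorted(bundles, key=lambda b: b.participant_id):
        pid = bundle.participant_id
        pdir = run_dir / "participants" / pid
        entry = old.get("participants", {}).get(pid)
        if entry is not None and (pdir / "surface_ed.vtk").exists() \
                and (pdir / "surface_es.vtk").exists():
            surf_ed = cio.read_mesh(pdir / "surface_ed.vtk")
            surf_es = cio.read_mesh(pdir / "surface_es.vtk")
            ed, es = int(entry["ed"]), int(entry["es"])
            pr = ParticipantResult(
                participant_id=pid, ed_frame=ed, es_frame=es,
                surface_ed=surf_ed, surface_es=surf_es,
                seg_record=phe.seg_phenotypes(bundle, ed, es),
                mesh_record=phe.mesh_phenotypes(pid, surf_ed, surf_es))
            if (pdir / "volmesh.vtk").exists():
                pr.volmesh = cio.read_mesh(pdir / "volmesh.vtk")
            result.participants[pid] = pr
        else:
            try:
                pr = process_participant(
                    bundle, template, config,
                    with_volumetric=config.build_volumetric)
            except Exception as err:
                result.failures.append(Failure(pid, type(err).__name__,
                                               str(err)))
                continue
            result.participants[pid] = pr
        if bundle.demographics is not None:
            demographics[pid] = bundle.demographics
    _cohort_stage(result, demographics, config)
    result.manifest = build_manifest(result, config)
    write_run(result, config, run_dir)
    return result
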