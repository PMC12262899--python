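"""Demographic binning, generalized Procrustes averaging and representative
meshes.

Kept participants are grouped into sex x 1-year age x 1-unit BMI bins (age
bins 44..85, BMI bins 15..50 kg/m²). All corresponded end-diastolic surface
meshes are superimposed rigidly — rotation and translation only, no scaling,
since representative anatomies must preserve absolute size — onto a
reference that is iteratively replaced by the mean shape until the
Procrustes distance between reference and mean drops to the tolerance
(1e-6). Each bin with at least three members is then averaged vertex-wise
and rebuilt into a labeled volumetric mesh with coordinates and fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Demographics
from .meshes import SurfaceMesh
from .surface import umeyama

AGE_BINS = range(44, 86)  # integer lower edges, 1-year width
BMI_BINS = range(15, 51)  # kg/m^2 lower edges, 1-unit width
MIN_BIN_MEMBERS = 3

OUT_OF_RANGE = "OUT_OF_RANGE"


def assign_bin(demographics: Demographics):
    """(sex, floor(age), floor(bmi)) bin key, or OUT_OF_RANGE."""
    age = int(np.floor(demographics.age))
    bmi = int(np.floor(demographics.bmi))
    if age not in AGE_BINS or bmi not in BMI_BINS:
        return OUT_OF_RANGE
    return (demographics.sex, age, bmi)


def procrustes_superimpose(mesh: SurfaceMesh, reference: SurfaceMesh):
    """Rigidly align a corresponded mesh to the reference.

    Returns ``(aligned_mesh, distance)`` where the distance is the centered
    vertex RMS between aligned mesh and reference, normalized by the
    reference's centroid size.
    """
    if mesh.vertices.shape != reference.vertices.shape or \
            not np.array_equal(mesh.faces, reference.faces):
        raise ValueError("meshes must share the template connectivity")
    _, R, t, _ = umeyama(mesh.vertices, reference.vertices, with_scale=False)
    out = mesh.copy()
    out.vertices = mesh.vertices @ R.T + t
    out.landmarks = dict(mesh.landmarks)
    return out, procrustes_distance(out.vertices, reference.vertices)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Centered vertex RMS of (a - b), normalized by b's centroid size."""
    size = np.sqrt(((b - b.mean(axis=0)) ** 2).sum(axis=1).mean())
    rms = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
    return float(rms / max(size, 1e-300))


@dataclass
class ProcrustesState:
    reference: np.ndarray
    iterations: int
    distance: float
    tolerance: float
    aligned: list = field(default_factory=list)


def gpa_reference(meshes: list, tolerance: float = 1e-6,
                  max_iterations: int = 100, first: int = 0) -> ProcrustesState:
    """Iterative mean-shape reference for generalized Procrustes analysis.

    Starts from ``meshes[first]``, superimposes all meshes, replaces the
    reference by the vertex-wise mean while the reference-to-mean Procrustes
    distance exceeds the tolerance.
    """
    if not meshes:
        raise ValueError("need at least one mesh")
    ref = meshes[first].copy()
    aligned = meshes
    dist = np.inf
    for it in range(1, max_iterations + 1):
        aligned = [procrustes_superimpose(m, ref)[0] for m in meshes]
        mean = ref.copy()
        mean.vertices = np.mean([m.vertices for m in aligned], axis=0)
        dist = procrustes_distance(mean.vertices, ref.vertices)
        ref = mean
        if dist <= tolerance:
            return ProcrustesState(reference=ref.vertices, iterations=it,
                                   distance=dist, tolerance=tolerance,
                                   aligned=aligned)
    raise RuntimeError(
        f"Procrustes reference loop did not converge in {max_iterations} "
        f"iterations (last distance {dist:.3e})")


def average_mesh(meshes: list, min_members: int = MIN_BIN_MEMBERS) -> SurfaceMesh:
    """Vertex-wise mean of corresponded (already aligned) meshes."""
    if len(meshes) < min_members:
        raise ValueError(
            f"bin has {len(meshes)} members; at least {min_members} required")
    first = meshes[0]
    for m in meshes[1:]:
        if m.vertices.shape != first.vertices.shape or \
                not np.array_equal(m.faces, first.faces):
            raise ValueError("meshes must share the template connectivity")
    out = first.copy()
    out.vertices = np.mean([m.vertices for m in meshes], axis=0)
    out.provenance = dict(first.provenance)
    out.provenance["averaged_from"] = len(meshes)
    return out


def build_representative_surfaces(surfaces: dict, demographics: dict,
                                  tolerance: float = 1e-6,
                                  min_members: int = MIN_BIN_MEMBERS):
    """Average the kept cohort per demographic bin.

    ``surfaces`` maps participant id to the ED surface mesh, ``demographics``
    to :class:`Demographics`. One global Procrustes reference is computed
    over all kept meshes (deterministic first-mesh initialization on sorted
    ids); each qualifying bin's aligned members are then averaged. Returns
    ``(representatives, state, manifest)`` where representatives maps bin key
    to the averaged surface.
    """
    ids = sorted(surfaces)
    if not ids:
        raise ValueError("empty cohort")
    state = gpa_reference([surfaces[i] for i in ids], tolerance=tolerance)
    aligned = dict(zip(ids, state.aligned))
    bins = {}
    for pid in ids:
        key = assign_bin(demographics[pid])
        if key == OUT_OF_RANGE:
            continue
        bins.setdefault(key, []).append(pid)
    reps, manifest = {}, []
    for key in sorted(bins):
        members = bins[key]
        entry = {"bin": key, "members": members, "built": False}
        if len(members) >= min_members:
            reps[key] = average_mesh([aligned[p] for p in members],
                                     min_members=min_members)
            entry["built"] = True
        manifest.append(entry)
    return reps, state, manifest


def cohort_associations(records: list, demographics: dict) -> dict:
    """Least-squares slopes of phenotypes on age and BMI, per sex and pooled,
    plus rank-sum p-values for sex differences.

    ``records`` are phenotype records (one per participant); slopes are in
    mL/year, g/year, mL/(kg/m²) etc. depending on the phenotype's unit.
    """
    import pandas as pd
    import statsmodels.api as smapi
    from scipy.stats import ranksums

    rows = []
    for r in records:
        d = demographics[r.participant_id]
        rows.append({"id": r.participant_id, "lvedv": r.lvedv,
                     "rvedv": r.rvedv, "lvm": r.lvm, "sex": d.sex,
                     "age": d.age, "bmi": d.bmi})
    df = pd.DataFrame(rows)
    out = {"slopes": {}, "sex_tests": {}}
    for pheno in ("lvedv", "rvedv", "lvm"):
        for cov in ("age", "bmi"):
            for sex in ("F", "M", "ALL"):
                sub = df if sex == "ALL" else df[df.sex == sex]
                if len(sub) < 3 or sub[cov].nunique() < 2:
                    continue
                X = smapi.add_constant(sub[cov].to_numpy())
                fit = smapi.OLS(sub[pheno].to_numpy(), X).fit()
                out["slopes"][(pheno, cov, sex)] = {
                    "slope": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p": float(fit.pvalues[1]),
                    "n": int(len(sub)),
                }
        f = df[df.sex == "F"][pheno]
        m = df[df.sex == "M"][pheno]
        if len(f) and len(m):
            stat, p = ranksums(f, m)
            out["sex_tests"][pheno] = {"stat": float(stat), "p": float(p)}
    return out
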