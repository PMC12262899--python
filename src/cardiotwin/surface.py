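"""Template-based biventricular surface fitting.

A fixed-connectivity idealized biventricular template (built from the same
analytic geometry as the phantom) is deformed to the contour/landmark point
cloud of one participant and frame. The deformation model is deliberately
simple and fully testable: per-vertex displacements regularized by the
squared norm of their graph Laplacian, minimized by alternating
nearest-neighbor correspondence with an exact sparse linear solve — an
iterative-closest-point scheme whose objective is non-increasing by
construction. Because every fit shares the template's connectivity, fitted
meshes are vertex-wise corresponded across participants, which is the
contract that makes Procrustes averaging meaningful downstream.

The RV epicardium is not visible in cine segmentations and is generated by
offsetting the RV endocardial surface 3 mm along outward vertex normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from . import contours as ct
from .core_io import CineView
from .geometry import GeometryParams, PhantomGeometry
from .meshes import SurfaceMesh

# surface region tags
LV_ENDO_S = "LV_ENDO"
LV_EPI_S = "LV_EPI"
RV_SEPTUM_S = "RV_SEPTUM_SURF"
RV_FW_S = "RV_FW_ENDO"
RV_EPI_S = "RV_EPI"
MV_RING = "MV_RING"
TV_RING = "TV_RING"
AO_RING = "AO_RING"
PV_RING = "PV_RING"
BASE_LID = "BASE_LID"  # epicardial base closure

CONTOUR_TO_REGION = {
    ct.LV_ENDO: LV_ENDO_S,
    ct.LV_EPI: LV_EPI_S,
    ct.RV_SEPTUM: RV_SEPTUM_S,
    ct.RV_FW: RV_FW_S,
}


@dataclass
class FitConfig:
    data_weight: float = 1.0
    smooth_weight: float = 1.0
    n_iterations: int = 15
    tol: float = 1e-4  # relative objective decrease
    correct_misalignment: bool = True
    shift_cap: float = 10.0  # mm

    def __post_init__(self):
        if self.data_weight < 0 or self.smooth_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


# ---------------------------------------------------------------------------
# template construction


def _revolve_surface(radius_of_z, z_apex: float, z_base: float,
                     n_long: int, n_circ: int):
    """Pole-capped surface of revolution about the z axis.

    Returns (vertices, faces, grid) with ``grid['pole']`` the apex vertex id
    and ``grid['rings']`` an (n_long, n_circ) id array from near-apex to base.
    """
    phis = np.linspace(0, np.pi / 2, n_long + 1)[1:]
    thetas = 2 * np.pi * np.arange(n_circ) / n_circ
    verts = [np.array([0.0, 0.0, z_apex])]
    rings = np.zeros((n_long, n_circ), dtype=np.int64)
    for i, phi in enumerate(phis):
        z = z_apex * np.cos(phi)
        r = radius_of_z(z)
        for j, th in enumerate(thetas):
            rings[i, j] = len(verts)
            verts.append(np.array([r * np.cos(th), r * np.sin(th), z]))
    faces = []
    for j in range(n_circ):
        faces.append([0, rings[0, j], rings[0, (j + 1) % n_circ]])
    for i in range(n_long - 1):
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            a, b = rings[i, j], rings[i, j2]
            c, d = rings[i + 1, j], rings[i + 1, j2]
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.array(verts), np.array(faces), {"pole": 0, "rings": rings}


def _fan_lid(vertices, ring_ids, center_point):
    """Fan triangulation closing a ring; returns (new_vertex, faces)."""
    faces = []
    n = len(ring_ids)
    for j in range(n):
        faces.append([len(vertices), ring_ids[(j + 1) % n], ring_ids[j]])
    return np.asarray(center_point, float), np.array(faces)


def _rv_rings(geom: PhantomGeometry, n_levels: int, n_sep: int, n_fw: int):
    """Sampled crescent boundary rings (septal arc + free-wall arc) per z."""
    p = geom.p
    c_rv = p.rv_outer_axes[2]
    z_deep = -c_rv
    # deepest level keeping a genuine two-arc crescent
    zs = np.linspace(-0.999 * c_rv, -1e-3, 400)
    ok = [z for z in zs if (cs := geom.rv_cross_section(z)) is not None
          and cs[3] > 0.05]
    z_trunc = 0.98 * min(ok)
    levels = np.linspace(z_trunc, -1e-6, n_levels + 1)
    rings = []
    for z in levels:
        r_sep, r_fw, d, phi_sep, phi_fw = geom.rv_cross_section(z)
        # septal arc on the LV-epicardial circle, from +y junction to -y
        ang_sep = np.linspace(phi_sep, -phi_sep, n_sep + 1)
        sep = np.column_stack([r_sep * np.cos(ang_sep), r_sep * np.sin(ang_sep),
                               np.full(n_sep + 1, z)])
        # free-wall arc on the RV outer circle, from -y junction back to +y;
        # seen from the RV center the LV lies toward -x
        ang_fw = np.linspace(-(np.pi - phi_fw), np.pi - phi_fw, n_fw + 1)
        fw = np.column_stack([d + r_fw * np.cos(ang_fw),
                              r_fw * np.sin(ang_fw),
                              np.full(n_fw + 1, z)])
        ring = np.concatenate([sep, fw[1:-1]])  # closed ring of n_sep+n_fw pts
        rings.append(ring)
    return np.array(rings)  # (n_levels+1, n_sep+n_fw, 3)


def build_template(geometry: GeometryParams | None = None,
                   n_long: int = 12, n_circ: int = 32,
                   rv_levels: int = 12, rv_sep: int = 10,
                   rv_fw: int = 22) -> SurfaceMesh:
    """Construct the idealized fixed-connectivity biventricular template.

    The template is a synthetic idealized surface derived from the package's
    analytic biventricular geometry (not a population atlas); correspondence
    plus regularized fitting, not atlas fidelity, is the contract.
    """
    geom = PhantomGeometry(geometry or GeometryParams())
    p = geom.p
    parts_v, parts_f, parts_r = [], [], []
    grids = {}
    offset = 0

    def add(verts, faces, regions):
        nonlocal offset
        parts_v.append(verts)
        parts_f.append(faces + offset)
        parts_r.extend(regions)
        base = offset
        offset += len(verts)
        return base

    # LV endocardium
    a_en, _, c_en = p.lv_endo_axes
    v, f, g = _revolve_surface(lambda z: geom.lv_ring_radius(z, "endo"),
                               -c_en, 0.0, n_long, n_circ)
    base = add(v, f, [LV_ENDO_S] * len(f))
    grids["lv_endo"] = {"pole": base, "rings": g["rings"] + base}
    # LV epicardium
    a_ep, _, c_ep = p.lv_epi_axes
    v, f, g = _revolve_surface(lambda z: geom.lv_ring_radius(z, "epi"),
                               -c_ep, 0.0, n_long, n_circ)
    base = add(v, f, [LV_EPI_S] * len(f))
    grids["lv_epi"] = {"pole": base, "rings": g["rings"] + base}
    # RV endocardium: stacked crescent rings, apex pole cap at the bottom
    rings = _rv_rings(geom, rv_levels, rv_sep, rv_fw)
    n_ring = rings.shape[1]
    rv_verts = [rings.reshape(-1, 3)]
    ring_ids = np.arange(rings.shape[0] * n_ring).reshape(rings.shape[0], n_ring)
    rv_faces, rv_regions = [], []
    septal_pt = np.zeros(n_ring, dtype=bool)
    septal_pt[: rv_sep + 1] = True
    for i in range(rings.shape[0] - 1):
        for j in range(n_ring):
            j2 = (j + 1) % n_ring
            a, b = ring_ids[i, j], ring_ids[i, j2]
            c, d = ring_ids[i + 1, j], ring_ids[i + 1, j2]
            reg = RV_SEPTUM_S if (septal_pt[j] and septal_pt[j2]) else RV_FW_S
            rv_faces.append([a, d, b])
            rv_faces.append([a, c, d])
            rv_regions.extend([reg, reg])
    pole_local = rings.shape[0] * n_ring
    pole_pos = rings[0].mean(axis=0)
    pole_pos[2] = rings[0, 0, 2] - 2.0
    rv_verts.append(pole_pos[None])
    for j in range(n_ring):
        j2 = (j + 1) % n_ring
        reg = RV_SEPTUM_S if (septal_pt[j] and septal_pt[j2]) else RV_FW_S
        rv_faces.append([pole_local, ring_ids[0, j2], ring_ids[0, j]])
        rv_regions.append(reg)
    rv_v = np.concatenate(rv_verts)
    base = add(rv_v, np.array(rv_faces), rv_regions)
    grids["rv_endo"] = {"pole": base + pole_local, "rings": ring_ids + base,
                        "n_sep": rv_sep}

    vertices = np.concatenate(parts_v)
    faces = np.concatenate(parts_f)
    regions = np.array(parts_r)

    # basal lids: LV endo orifice (mitral + aortic), LV epi closure, RV orifice
    def lid(ring_ids_row, center, split=None):
        nonlocal vertices, faces, regions
        cpt, f = _fan_lid(vertices, ring_ids_row, center)
        vertices = np.concatenate([vertices, cpt[None]])
        if split is None:
            reg = [lid_region] * len(f)
        else:
            reg = split(f)
        faces = np.concatenate([faces, f])
        regions = np.concatenate([regions, reg])
        return len(vertices) - 1

    endo_top = grids["lv_endo"]["rings"][-1]
    ao_c = p.ao_center

    lid_region = MV_RING

    def split_lv(f):
        out = []
        for tri in f:
            cen = vertices[tri].mean(axis=0) if max(tri) < len(vertices) else None
            # centroid using ring vertices only (center vertex appended after)
            pts = [vertices[t] for t in tri if t < len(vertices)]
            cen = np.mean(pts, axis=0)
            inside_ao = (cen[0] - ao_c[0]) ** 2 + (cen[1] - ao_c[1]) ** 2 \
                <= p.ao_radius ** 2
            out.append(AO_RING if inside_ao else MV_RING)
        return out

    mv_center = lid(endo_top, np.array([0.0, 0.0, 0.0]), split=split_lv)
    grids["lv_endo"]["lid_center"] = mv_center

    lid_region = BASE_LID
    epi_top = grids["lv_epi"]["rings"][-1]
    epi_center = lid(epi_top, np.array([0.0, 0.0, 0.0]))
    grids["lv_epi"]["lid_center"] = epi_center

    rv_top = grids["rv_endo"]["rings"][-1]
    rv_centroid = vertices[rv_top].mean(axis=0)

    def split_rv_lid(f):
        out = []
        for tri in f:
            pts = [vertices[t] for t in tri if t < len(vertices)]
            cen = np.mean(pts, axis=0)
            out.append(PV_RING if cen[1] > rv_centroid[1] else TV_RING)
        return out

    rv_center = lid(rv_top, rv_centroid, split=split_rv_lid)
    grids["rv_endo"]["lid_center"] = rv_center

    # named landmark vertices, keyed VIEW:NAME for alignment correspondences
    landmarks = {}
    thetas = {CineView.LAX2CH: np.pi / 2, CineView.LAX3CH: np.deg2rad(30.0),
              CineView.LAX4CH: 0.0}
    for view, th in thetas.items():
        e = np.array([np.cos(th), np.sin(th), 0.0])
        ring_pts = vertices[endo_top]
        for name, direction in (("MV_1", -e), ("MV_2", e)):
            vid = endo_top[np.argmax(ring_pts @ direction)]
            landmarks[f"{view.value}:{name}"] = int(vid)
    landmarks[f"{CineView.LAX2CH.value}:APEX"] = int(grids["lv_epi"]["pole"])
    e3 = np.array([np.cos(np.deg2rad(30.0)), np.sin(np.deg2rad(30.0)), 0.0])
    for name, target in (("AO_1", ao_c - p.ao_radius * e3),
                         ("AO_2", ao_c + p.ao_radius * e3)):
        vid = endo_top[np.argmin(np.linalg.norm(vertices[endo_top] - target,
                                                axis=1))]
        landmarks[f"{CineView.LAX3CH.value}:{name}"] = int(vid)
    rv_ring_pts = vertices[rv_top]
    for name, target in (("TV_1", np.array([36.0, 0.0, 0.0])),
                         ("TV_2", np.array([44.0, 0.0, 0.0]))):
        vid = rv_top[np.argmin(np.linalg.norm(rv_ring_pts - target, axis=1))]
        landmarks[f"{CineView.LAX4CH.value}:{name}"] = int(vid)

    mesh = SurfaceMesh(vertices, faces, regions, landmarks=landmarks,
                       provenance={"grids": grids,
                                   "template_dims": (n_long, n_circ, rv_levels,
                                                     rv_sep, rv_fw)})
    return mesh


# ---------------------------------------------------------------------------
# rigid / similarity registration


def umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Least-squares similarity (or rigid) transform src -> dst.

    Returns ``(scale, R, t, rms)`` minimizing ``||s R src + t - dst||``.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (xs ** 2).sum() / len(src)
    scale = float(np.trace(np.diag(S) @ D) / var_s) if with_scale else 1.0
    t = mu_d - scale * R @ mu_s
    res = scale * src @ R.T + t - dst
    rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    return scale, R, t, rms


def align_template(template: SurfaceMesh, landmark_sets: dict):
    """Similarity transform initializing the fit from landmark pairs.

    ``landmark_sets`` maps :class:`CineView` to extracted
    :class:`~cardiotwin.contours.LandmarkSet` objects. Requires at least 3
    non-collinear correspondences with template landmark vertices.
    """
    src, dst = [], []
    for view, lm in landmark_sets.items():
        if lm is None:
            continue
        for name, pt in lm.points.items():
            key = f"{view.value}:{name}"
            if key in template.landmarks:
                src.append(template.vertices[template.landmarks[key]])
                dst.append(pt)
    src, dst = np.array(src), np.array(dst)
    if len(src) < 3:
        raise ValueError(f"need >=3 landmark correspondences, got {len(src)}")
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-6) < 2:
        raise ValueError("landmark correspondences are collinear")
    return umeyama(src, dst, with_scale=True)


# ---------------------------------------------------------------------------
# misalignment correction


def correct_misalignment(contour_groups: dict, surface: SurfaceMesh,
                         shift_cap: float = 10.0, n_iter: int = 3) -> dict:
    """Per-slice in-plane shifts minimizing point-to-surface distance.

    ``contour_groups`` maps a group key (view, slice) to a dict with
    ``contours`` (list of :class:`~cardiotwin.contours.Contour`) and
    ``basis`` (2x3 in-plane unit vectors). Returns key -> shift (3,) in mm;
    contour points are shifted in place.
    """
    trees = {}
    for region in set(CONTOUR_TO_REGION.values()):
        ids = surface.region_vertex_ids(region)
        if len(ids):
            trees[region] = (cKDTree(surface.vertices[ids]), ids)
    shifts = {}
    for key, group in contour_groups.items():
        basis = np.asarray(group["basis"], float)
        total = np.zeros(3)
        for _ in range(n_iter):
            deltas = []
            for c in group["contours"]:
                region = CONTOUR_TO_REGION[c.structure]
                if region not in trees:
                    continue
                tree, ids = trees[region]
                _, nn = tree.query(c.points + total)
                deltas.append(surface.vertices[ids[nn]] - (c.points + total))
            if not deltas:
                break
            d = np.concatenate(deltas).mean(axis=0)
            total += basis.T @ (basis @ d)  # in-plane projection
        norm = np.linalg.norm(total)
        if norm > shift_cap:
            total *= shift_cap / norm
        shifts[key] = total
        for c in group["contours"]:
            c.points = c.points + total
    return shifts


# ---------------------------------------------------------------------------
# fitting


def _graph_laplacian(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    A = sparse.coo_matrix((w, (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sparse.diags(deg) - A


@dataclass
class FitResult:
    mesh: SurfaceMesh
    objective_trace: list
    converged: bool
    region_rms: dict = field(default_factory=dict)


def fit_surface(template: SurfaceMesh, contours: list, landmarks: dict,
                config: FitConfig | None = None) -> FitResult:
    """Deform the template to the contour point cloud.

    Minimizes ``sum_p ||x_{m(p)} - p||^2 + lambda ||L d||^2`` where ``m`` is
    the nearest-vertex correspondence within the matching region, ``d`` the
    displacement from the similarity-aligned template and ``L`` the uniform
    graph Laplacian; correspondences and the exact sparse solve alternate,
    so the objective never increases.
    """
    config = config or FitConfig()
    mesh = template.copy()
    if landmarks:
        s, R, t, _ = align_template(template, landmarks)
        mesh.vertices = s * mesh.vertices @ R.T + t
    x0 = mesh.vertices.copy()
    n = len(x0)
    L = _graph_laplacian(n, mesh.faces)
    LtL = (L.T @ L).tocsc() * config.smooth_weight
    region_ids = {r: mesh.region_vertex_ids(r)
                  for r in set(CONTOUR_TO_REGION.values())}
    pts_by_region = {}
    for c in contours:
        region = CONTOUR_TO_REGION[c.structure]
        pts_by_region.setdefault(region, []).append(np.atleast_2d(c.points))
    pts_by_region = {r: np.concatenate(v) for r, v in pts_by_region.items()
                     if len(region_ids.get(r, ())) > 0}
    if ct.LV_ENDO not in [c.structure for c in contours] or \
       ct.LV_EPI not in [c.structure for c in contours]:
        raise ValueError("LV endo and epi contours are required for fitting")

    d = np.zeros_like(x0)
    trace = []
    converged = False
    w = config.data_weight
    for _ in range(config.n_iterations):
        x = x0 + d
        counts = np.zeros(n)
        rhs = np.zeros((n, 3))
        data_term = 0.0
        for region, pts in pts_by_region.items():
            ids = region_ids[region]
            tree = cKDTree(x[ids])
            dist, nn = tree.query(pts)
            vid = ids[nn]
            np.add.at(counts, vid, w)
            np.add.at(rhs, vid, w * (pts - x0[vid]))
            data_term += w * float((dist ** 2).sum())
        obj = data_term + config.smooth_weight * float(np.sum((L @ d) ** 2))
        trace.append(obj)
        if len(trace) >= 2 and trace[-2] - trace[-1] <= config.tol * max(trace[-2], 1e-12):
            converged = True
            break
        A = sparse.diags(counts).tocsc() + LtL
        solver = splu(A.tocsc())
        d = np.column_stack([solver.solve(rhs[:, k]) for k in range(3)])
    mesh.vertices = x0 + d
    # final per-region RMS point-to-nearest-vertex distance
    region_rms = {}
    for region, pts in pts_by_region.items():
        ids = region_ids[region]
        dist, _ = cKDTree(mesh.vertices[ids]).query(pts)
        region_rms[region] = float(np.sqrt((dist ** 2).mean()))
    mesh.provenance = dict(template.provenance)
    return FitResult(mesh=mesh, objective_trace=trace, converged=converged,
                     region_rms=region_rms)


def hemi_ellipsoid_patch(a: float = 35.0, b: float = 25.0, c: float = 50.0,
                         n_long: int = 40, n_circ: int = 52,
                         region: str = RV_FW_S) -> SurfaceMesh:
    """Open hemi-ellipsoidal test patch (apex pole at z=-c, rim near z=0).

    A standard synthetic fixture for surface-offset and distance checks.
    """
    phis = np.linspace(0.04, np.pi / 2, n_long)
    ths = 2 * np.pi * np.arange(n_circ) / n_circ
    verts = [np.array([0.0, 0.0, -c])]
    rings = []
    for phi in phis:
        ring = []
        for th in ths:
            ring.append(len(verts))
            verts.append(np.array([a * np.sin(phi) * np.cos(th),
                                   b * np.sin(phi) * np.sin(th),
                                   -c * np.cos(phi)]))
        rings.append(ring)
    faces = [[0, rings[0][j], rings[0][(j + 1) % n_circ]]
             for j in range(n_circ)]
    for i in range(n_long - 2):
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            faces += [[rings[i][j], rings[i][j2], rings[i + 1][j2]],
                      [rings[i][j], rings[i + 1][j2], rings[i + 1][j]]]
    faces = np.array(faces)
    return SurfaceMesh(np.array(verts), faces, np.full(len(faces), region))


DEFAULT_SCHEDULE = ((1.0, 10), (0.3, 10), (0.08, 25))


def fit_surface_multiscale(template: SurfaceMesh, contours: list,
                           landmarks: dict,
                           schedule=DEFAULT_SCHEDULE,
                           correct_slices: bool = True,
                           shift_cap: float = 10.0) -> FitResult:
    """Coarse-to-fine fit: decreasing smoothness stages, each seeded with the
    previous stage's mesh (landmark alignment only at the first stage).

    When ``correct_slices`` is set, per-slice in-plane misalignment
    correction runs against the first-stage fit before refinement.
    """
    mesh = template
    result = None
    for stage, (lam, iters) in enumerate(schedule):
        cfg = FitConfig(smooth_weight=lam, n_iterations=iters, tol=1e-7,
                        shift_cap=shift_cap)
        result = fit_surface(mesh, contours, landmarks if stage == 0 else {},
                             cfg)
        mesh = result.mesh
        if stage == 0 and correct_slices:
            groups = group_contours_by_slice(contours)
            correct_misalignment(groups, mesh, shift_cap=shift_cap)
    return result


def group_contours_by_slice(contours: list) -> dict:
    """Group contours by (view, slice) with the slice's in-plane basis."""
    groups = {}
    for c in contours:
        key = (c.view.value, c.slice_index)
        if key not in groups:
            pts = c.points
            groups[key] = {"contours": [], "basis": None, "_pts": pts}
        groups[key]["contours"].append(c)
    for key, g in groups.items():
        pts = np.concatenate([np.atleast_2d(c.points) for c in g["contours"]])
        c0 = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c0, full_matrices=False)
        g["basis"] = vt[:2]
        g.pop("_pts")
    return groups


# ---------------------------------------------------------------------------
# RV epicardium


def generate_rv_epicardium(surface: SurfaceMesh,
                           thickness: float = 3.0) -> SurfaceMesh:
    """Extend the RV endocardium outward along vertex normals.

    Appends an ``RV_EPI`` region whose vertices are the RV endocardial
    vertices displaced by ``thickness`` mm along area-weighted outward
    vertex normals (3 mm default, consistent with experimental RV wall
    thickness measurements). Offset self-intersections are flagged in
    ``provenance['rv_epi_self_intersections']``.
    """
    rv_faces_mask = np.isin(surface.face_region, [RV_SEPTUM_S, RV_FW_S])
    if not rv_faces_mask.any():
        raise ValueError("no RV endocardial regions present")
    faces = surface.faces[rv_faces_mask]
    regs = surface.face_region[rv_faces_mask]
    ids = np.unique(faces)
    sub = trimesh.Trimesh(vertices=surface.vertices, faces=faces, process=False)
    normals = sub.vertex_normals.copy()
    norms = np.linalg.norm(normals[ids], axis=1)
    if np.any(norms < 1e-8):
        raise ValueError("degenerate vertex normals on the RV endocardium")
    # orient outward: the offset must enlarge the enclosed region
    centroid = surface.vertices[ids].mean(axis=0)
    outward = np.einsum("ij,ij->i",
                        normals[ids], surface.vertices[ids] - centroid)
    if np.median(outward) < 0:
        normals = -normals
    out = surface.copy()
    remap = {old: len(out.vertices) + k for k, old in enumerate(ids)}
    epi_verts = surface.vertices[ids] + thickness * normals[ids]
    out.vertices = np.concatenate([out.vertices, epi_verts])
    epi_faces = np.vectorize(remap.get)(faces)
    out.faces = np.concatenate([out.faces, epi_faces])
    out.face_region = np.concatenate([out.face_region,
                                      np.full(len(epi_faces), RV_EPI_S)])
    grids = dict(out.provenance.get("grids", {}))
    out.provenance["rv_epi_map"] = {int(k): int(v) for k, v in remap.items()}
    from .volmesh import detect_self_intersections
    pairs = detect_self_intersections(SurfaceMesh(
        out.vertices, epi_faces, np.full(len(epi_faces), RV_EPI_S)))
    out.provenance["rv_epi_self_intersections"] = pairs
    return out
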