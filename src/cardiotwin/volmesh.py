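"""Tetrahedral mesh construction and checks.

The ventricular walls are meshed by extruding the matched endocardial and
epicardial surface grids into wedge stacks split into tetrahedra
(:func:`cardiotwin.meshes.extrude_wall`), which yields a conforming, labeled
mesh directly — the same role an external meshing tool plays in large-scale
pipelines, exposed behind the narrow :func:`tetrahedralize` contract so a
different backend can be plugged in. A built-in Delaunay-carve fallback
handles generic closed surfaces (exact on convex polyhedra).

Region labels follow the six-region scheme: LV myocardium, RV myocardium
and the four valve lids (mitral, aortic, tricuspid, pulmonary).
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from . import surface as sf
from .geometry import GeometryParams, PhantomGeometry
from .meshes import (SurfaceMesh, VolumetricMesh, extrude_wall, fix_orientation,
                     merge_volumetric, point_surface_distance, points_inside,
                     surface_boundary_vertices, tet_volumes)

# volumetric region tags
LV_MYO_T = "LV_MYO"
RV_MYO_T = "RV_MYO"
MITRAL_VALVE = "MITRAL_VALVE"
AORTIC_VALVE = "AORTIC_VALVE"
TRICUSPID_VALVE = "TRICUSPID_VALVE"
PULMONARY_VALVE = "PULMONARY_VALVE"

VALVE_TAGS = (MITRAL_VALVE, AORTIC_VALVE, TRICUSPID_VALVE, PULMONARY_VALVE)
LID_TO_VALVE = {sf.MV_RING: MITRAL_VALVE, sf.AO_RING: AORTIC_VALVE,
                sf.TV_RING: TRICUSPID_VALVE, sf.PV_RING: PULMONARY_VALVE}


# ---------------------------------------------------------------------------
# triangle-triangle intersection


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-10) -> bool:
    """Exact-ish triangle-triangle intersection (interval test on the
    intersection line of the two planes; coplanar pairs via 2D projection)."""
    v0, v1, v2 = t1
    u0, u1, u2 = t2
    n2 = np.cross(u1 - u0, u2 - u0)
    d2 = -n2 @ u0
    dv = np.array([n2 @ v0 + d2, n2 @ v1 + d2, n2 @ v2 + d2])
    dv[np.abs(dv) < eps] = 0.0
    if np.all(dv > 0) or np.all(dv < 0):
        return False
    n1 = np.cross(v1 - v0, v2 - v0)
    d1 = -n1 @ v0
    du = np.array([n1 @ u0 + d1, n1 @ u1 + d1, n1 @ u2 + d1])
    du[np.abs(du) < eps] = 0.0
    if np.all(du > 0) or np.all(du < 0):
        return False
    if np.all(dv == 0):  # coplanar
        return _coplanar_tri_tri(t1, t2, n1)
    direction = np.cross(n1, n2)
    axis = np.argmax(np.abs(direction))

    def interval(tri, dists):
        proj = tri[:, axis]
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if dists[i] == 0:
                pts.append(proj[i])
            if dists[i] * dists[j] < 0:
                t = dists[i] / (dists[i] - dists[j])
                pts.append(proj[i] + t * (proj[j] - proj[i]))
        return min(pts), max(pts)

    a1, b1 = interval(t1, dv)
    a2, b2 = interval(t2, du)
    return max(a1, a2) <= min(b1, b2) - eps


def _coplanar_tri_tri(t1, t2, n) -> bool:
    drop = np.argmax(np.abs(n))
    keep = [k for k in range(3) if k != drop]
    p1, p2 = t1[:, keep], t2[:, keep]

    def seg_int(a, b, c, d):
        r, s = b - a, d - c
        den = r[0] * s[1] - r[1] * s[0]
        if abs(den) < 1e-14:
            return False
        t = ((c - a)[0] * s[1] - (c - a)[1] * s[0]) / den
        u = ((c - a)[0] * r[1] - (c - a)[1] * r[0]) / den
        return 0 < t < 1 and 0 < u < 1

    for i in range(3):
        for j in range(3):
            if seg_int(p1[i], p1[(i + 1) % 3], p2[j], p2[(j + 1) % 3]):
                return True

    def inside(pt, tri):
        s = 0
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            cross = (b[0] - a[0]) * (pt[1] - a[1]) - (b[1] - a[1]) * (pt[0] - a[0])
            if abs(cross) < 1e-14:
                return False
            s += np.sign(cross)
        return abs(s) == 3

    return inside(p1.mean(axis=0), p2) or inside(p2.mean(axis=0), p1)


def candidate_pairs(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """AABB spatial-hash pruning: pairs of triangles with overlapping boxes
    that do not share a vertex."""
    tri = vertices[faces]
    lo, hi = tri.min(axis=1), tri.max(axis=1)
    cell = max(float(np.median(hi - lo)), 1e-6)
    buckets = {}
    for f in range(len(faces)):
        c0 = np.floor(lo[f] / cell).astype(int)
        c1 = np.floor(hi[f] / cell).astype(int)
        for i in range(c0[0], c1[0] + 1):
            for j in range(c0[1], c1[1] + 1):
                for k in range(c0[2], c1[2] + 1):
                    buckets.setdefault((i, j, k), []).append(f)
    pairs = set()
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                f, g = members[a], members[b]
                if set(faces[f]) & set(faces[g]):
                    continue
                if np.all(lo[f] <= hi[g]) and np.all(lo[g] <= hi[f]):
                    pairs.add((min(f, g), max(f, g)))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def detect_self_intersections(surface: SurfaceMesh) -> list:
    """All pairs of non-adjacent triangles that intersect each other."""
    tri = surface.vertices[surface.faces]
    out = []
    for f, g in candidate_pairs(surface.vertices, surface.faces):
        if _tri_tri_intersect(tri[f], tri[g]):
            out.append((int(f), int(g)))
    return out


# ---------------------------------------------------------------------------
# generic tetrahedralization (pluggable backend + Delaunay-carve fallback)


def _is_closed(faces: np.ndarray) -> bool:
    edges = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                    faces[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def tetrahedralize(surface: SurfaceMesh, target_edge: float = 5.0,
                   backend=None, check_intersections: bool = True) -> VolumetricMesh:
    """Fill a closed, intersection-free surface with tetrahedra.

    ``backend(surface, target_edge) -> (nodes, tets)`` may delegate to an
    external mesher; the built-in fallback inserts an interior point grid at
    ``target_edge`` spacing, computes a Delaunay tetrahedralization of
    surface plus interior points and discards tetrahedra whose centroid
    falls outside the surface (exact for convex polyhedra).
    """
    if not _is_closed(surface.faces):
        raise ValueError("surface is not closed; cannot tetrahedralize")
    if check_intersections:
        bad = detect_self_intersections(surface)
        if bad:
            raise ValueError(
                f"surface has {len(bad)} self-intersecting triangle pairs "
                "(see detect_self_intersections)")
    if backend is not None:
        nodes, tets = backend(surface, target_edge)
    else:
        lo = surface.vertices.min(axis=0)
        hi = surface.vertices.max(axis=0)
        axes = [np.arange(lo[i] + target_edge / 2, hi[i], target_edge)
                for i in range(3)]
        if all(len(a) for a in axes):
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
            inside = points_inside(grid, surface.vertices, surface.faces)
            interior = grid[inside]
        else:
            interior = np.empty((0, 3))
        nodes = np.concatenate([surface.vertices, interior])
        dela = Delaunay(nodes)
        tets = dela.simplices
        centroids = nodes[tets].mean(axis=1)
        keep = points_inside(centroids, surface.vertices, surface.faces)
        tets = tets[keep]
    tets = fix_orientation(nodes, tets)
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return VolumetricMesh(nodes[used], remap[tets],
                          np.full(len(tets), "INTERIOR"))


# ---------------------------------------------------------------------------
# region labeling


def label_regions(volmesh: VolumetricMesh, surface: SurfaceMesh,
                  lid_thickness: float = 2.0) -> VolumetricMesh:
    """Assign the six-region tags by point-in-region classification.

    Valve lids claim elements whose centroids lie within the lid patch slab;
    remaining elements inside the LV epicardial envelope but outside the LV
    cavity become LV myocardium; elements between RV endo and RV epi become
    RV myocardium. Every element must be claimed exactly once; leftovers
    raise with their element ids.
    """
    cen = volmesh.centroids()
    tags = np.array([""] * volmesh.n_elems, dtype=object)
    for lid_region, valve in LID_TO_VALVE.items():
        faces = surface.region_faces(lid_region)
        if not len(faces):
            continue
        dist = point_surface_distance(cen, surface.vertices, faces)
        claim = (dist <= lid_thickness * 0.75) & (tags == "")
        tags[claim] = valve
    free = tags == ""
    inside_epi = points_inside(
        cen[free], surface.vertices,
        surface.region_faces(sf.LV_EPI_S, sf.BASE_LID))
    inside_cav = points_inside(
        cen[free], surface.vertices,
        surface.region_faces(sf.LV_ENDO_S, sf.MV_RING, sf.AO_RING))
    lv_idx = np.where(free)[0][inside_epi & ~inside_cav]
    tags[lv_idx] = LV_MYO_T
    free = tags == ""
    if (surface.face_region == sf.RV_EPI_S).any():
        d_endo = point_surface_distance(
            cen[free], surface.vertices,
            surface.region_faces(sf.RV_SEPTUM_S, sf.RV_FW_S))
        # between endo and the 3 mm epi offset (plus slack for curvature)
        rv_idx = np.where(free)[0][d_endo <= 4.0]
        tags[rv_idx] = RV_MYO_T
    leftover = np.where(tags == "")[0]
    if len(leftover):
        raise ValueError(f"{len(leftover)} unlabeled elements, e.g. "
                         f"{leftover[:10].tolist()}")
    out = volmesh
    out.elem_tag = tags.astype(str)
    return out


# ---------------------------------------------------------------------------
# quality


def mesh_quality(volmesh: VolumetricMesh, n_worst: int = 10) -> dict:
    """Radius-ratio quality (3 r_in / r_circ, 1 = regular tet) per element."""
    p = volmesh.nodes[volmesh.tets]
    vol = np.abs(tet_volumes(volmesh.nodes, volmesh.tets))
    areas = np.zeros(len(p))
    for (i, j, k) in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        areas += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1)
    r_in = 3.0 * vol / np.maximum(areas, 1e-300)
    # circumcenter from the linear system 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2
    A = 2.0 * (p[:, 1:] - p[:, :1])
    b = (p[:, 1:] ** 2).sum(-1) - (p[:, :1] ** 2).sum(-1)
    c = np.linalg.solve(A, b[..., None])[..., 0]
    r_circ = np.linalg.norm(c - p[:, 0], axis=1)
    q = 3.0 * r_in / np.maximum(r_circ, 1e-300)
    order = np.argsort(q)
    return {"quality": q, "min": float(q.min()), "mean": float(q.mean()),
            "worst_elements": order[:n_worst].tolist()}


# ---------------------------------------------------------------------------
# pipeline volumetric construction (matched-grid extrusion)


def _lv_pattern(n_long: int, n_circ: int):
    """Local faces for [pole, ring_0..ring_{n_long-1} x n_circ] ordering."""
    rings = 1 + np.arange(n_long * n_circ).reshape(n_long, n_circ)
    faces = []
    for j in range(n_circ):
        faces.append([0, rings[0, j], rings[0, (j + 1) % n_circ]])
    for i in range(n_long - 1):
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            faces.append([rings[i, j], rings[i, j2], rings[i + 1, j2]])
            faces.append([rings[i, j], rings[i + 1, j2], rings[i + 1, j]])
    return np.array(faces), rings


def _rv_pattern(n_levels: int, n_ring: int):
    """Local faces for [ring_0..ring_{n_levels} x n_ring, pole] ordering."""
    rings = np.arange((n_levels + 1) * n_ring).reshape(n_levels + 1, n_ring)
    pole = (n_levels + 1) * n_ring
    faces = []
    for i in range(n_levels):
        for j in range(n_ring):
            j2 = (j + 1) % n_ring
            faces.append([rings[i, j], rings[i + 1, j2], rings[i, j2]])
            faces.append([rings[i, j], rings[i + 1, j], rings[i + 1, j2]])
    for j in range(n_ring):
        j2 = (j + 1) % n_ring
        faces.append([pole, rings[0, j2], rings[0, j]])
    return np.array(faces), rings, pole


def build_biventricular_mesh(surface: SurfaceMesh, n_layers: int = 4,
                             lid_thickness: float = 2.0) -> VolumetricMesh:
    """Extrude a fitted surface (with RV epicardium) into a labeled tet mesh.

    LV wall sweeps the matched endo/epi grids; the RV wall sweeps the RV
    endocardium to its 3 mm offset; each valve lid patch is extruded by
    ``lid_thickness`` along its outward (basal) normal. Node sets needed by
    the coordinate solver (endo/epi/base/apex) are recorded.
    """
    grids = surface.provenance.get("grids")
    if grids is None:
        raise ValueError("surface lacks template grid provenance")
    n_long, n_circ = grids["lv_endo"]["rings"].shape
    endo_ids = np.concatenate([[grids["lv_endo"]["pole"]],
                               grids["lv_endo"]["rings"].ravel()])
    epi_ids = np.concatenate([[grids["lv_epi"]["pole"]],
                              grids["lv_epi"]["rings"].ravel()])
    lv_faces, _ = _lv_pattern(n_long, n_circ)
    lv_nodes, lv_tets, lv_layer = extrude_wall(
        surface.vertices[endo_ids], surface.vertices[epi_ids], lv_faces, n_layers)

    rv_rings = grids["rv_endo"]["rings"]
    n_levels = rv_rings.shape[0] - 1
    n_ring = rv_rings.shape[1]
    rv_endo_ids = np.concatenate([rv_rings.ravel(), [grids["rv_endo"]["pole"]]])
    rv_epi_map = surface.provenance.get("rv_epi_map")
    if rv_epi_map is None:
        raise ValueError("run generate_rv_epicardium before volumetric meshing")
    rv_epi_ids = np.array([rv_epi_map[int(i)] for i in rv_endo_ids])
    rv_faces, _, _ = _rv_pattern(n_levels, n_ring)
    rv_nodes, rv_tets, rv_layer = extrude_wall(
        surface.vertices[rv_endo_ids], surface.vertices[rv_epi_ids],
        rv_faces, max(1, n_layers // 2))

    parts = [(lv_nodes, lv_tets, LV_MYO_T), (rv_nodes, rv_tets, RV_MYO_T)]

    # valve lids: extrude each patch along its outward basal normal
    apex = surface.vertices[grids["lv_epi"]["pole"]]
    for lid_region, valve in LID_TO_VALVE.items():
        faces = surface.region_faces(lid_region)
        if not len(faces):
            continue
        ids = np.unique(faces)
        local = -np.ones(surface.n_vertices, dtype=np.int64)
        local[ids] = np.arange(len(ids))
        lfaces = local[faces]
        verts = surface.vertices[ids]
        patch = trimesh.Trimesh(vertices=verts, faces=lfaces, process=False)
        normal = patch.face_normals.mean(axis=0)
        normal /= np.linalg.norm(normal)
        if normal @ (verts.mean(axis=0) - apex) < 0:
            normal = -normal
        nodes_l, tets_l, _ = extrude_wall(verts, verts + lid_thickness * normal,
                                          lfaces, 1)
        parts.append((nodes_l, tets_l, valve))

    nodes, tets, tags, maps = merge_volumetric(parts)
    vm = VolumetricMesh(nodes, tets, tags)

    lv_map, rv_map = maps[0], maps[1]
    n_lv_surf = len(endo_ids)
    n_rv_surf = len(rv_endo_ids)
    node_sets = {
        "LV_ENDO": lv_map[lv_layer == 0],
        "LV_EPI": lv_map[lv_layer == n_layers],
        "RV_ENDO": rv_map[rv_layer == 0],
        "RV_EPI": rv_map[rv_layer == rv_layer.max()],
    }
    # basal rim: extrusions of the open-boundary vertices of both walls
    lv_rim_local = surface_boundary_vertices(lv_faces)
    rim = [lv_map[lv_rim_local + k * n_lv_surf] for k in range(n_layers + 1)]
    rv_rim_local = surface_boundary_vertices(rv_faces)
    rim += [rv_map[rv_rim_local + k * n_rv_surf]
            for k in range(rv_layer.max() + 1)]
    node_sets["BASE"] = np.unique(np.concatenate(rim))
    d_apex = np.linalg.norm(nodes - apex, axis=1)
    node_sets["APEX"] = np.where(d_apex <= max(2.0, d_apex.min() + 1e-9))[0]
    vm.node_sets = node_sets
    vm.provenance = {"lid_thickness": lid_thickness}
    return vm


def idealized_lv_mesh(geometry: GeometryParams | None = None,
                      n_long: int = 11, n_circ: int = 32,
                      n_layers: int = 10) -> VolumetricMesh:
    """Idealized truncated-ellipsoid LV wall tet mesh (~20k elements at the
    defaults: 10 transmural layers of ~1 mm through the 10 mm wall)."""
    geom = PhantomGeometry(geometry or GeometryParams())
    tmpl = sf.build_template(geom.p, n_long=n_long, n_circ=n_circ)
    grids = tmpl.provenance["grids"]
    endo_ids = np.concatenate([[grids["lv_endo"]["pole"]],
                               grids["lv_endo"]["rings"].ravel()])
    epi_ids = np.concatenate([[grids["lv_epi"]["pole"]],
                              grids["lv_epi"]["rings"].ravel()])
    faces, _ = _lv_pattern(n_long, n_circ)
    nodes, tets, layer = extrude_wall(tmpl.vertices[endo_ids],
                                      tmpl.vertices[epi_ids], faces, n_layers)
    vm = VolumetricMesh(nodes, tets, np.full(len(tets), LV_MYO_T))
    rim_local = surface_boundary_vertices(faces)
    n_surf = len(endo_ids)
    rim = np.unique(np.concatenate(
        [rim_local + k * n_surf for k in range(n_layers + 1)]))
    apex = tmpl.vertices[grids["lv_epi"]["pole"]]
    d_apex = np.linalg.norm(nodes - apex, axis=1)
    vm.node_sets = {
        "LV_ENDO": np.where(layer == 0)[0],
        "LV_EPI": np.where(layer == n_layers)[0],
        "RV_ENDO": np.array([], dtype=np.int64),
        "RV_EPI": np.array([], dtype=np.int64),
        "BASE": rim,
        "APEX": np.where(d_apex <= max(2.0, d_apex.min() + 1e-9))[0],
    }
    return vm
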