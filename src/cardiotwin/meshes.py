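"""Shared mesh containers and low-level tetrahedral utilities.

Two containers travel through the pipeline: a fixed-connectivity triangulated
biventricular :class:`SurfaceMesh` (template correspondence is the contract
that makes cross-participant averaging meaningful) and a labeled
:class:`VolumetricMesh` of tetrahedra carrying universal ventricular
coordinates and fiber triads as named point/cell data.

The extrusion mesher here converts a pair of corresponded triangulated
surfaces (e.g. endocardium and epicardium sharing one vertex grid) into a
conforming tetrahedral wall mesh: each surface triangle sweeps a stack of
wedges, and every wedge is split into three tetrahedra using the
minimal-global-index diagonal rule, which guarantees that the quad faces
shared by neighboring wedges are split identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


# ---------------------------------------------------------------------------
# containers


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-face region labels and named landmarks.

    ``vertices`` are world millimetres. ``face_region`` holds string region
    tags (e.g. ``LV_ENDO``, ``RV_FW_ENDO``, ``MV_RING``). ``landmarks`` maps
    landmark names to vertex indices. Fitted meshes keep the template's
    connectivity, so two fits are vertex-wise corresponded.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_region: np.ndarray  # (n_faces,) array of str
    landmarks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_region = np.asarray(self.face_region)
        if len(self.face_region) != len(self.faces):
            raise ValueError("face_region length must match faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def region_faces(self, *regions: str) -> np.ndarray:
        mask = np.isin(self.face_region, list(regions))
        return self.faces[mask]

    def region_vertex_ids(self, *regions: str) -> np.ndarray:
        return np.unique(self.region_faces(*regions))

    def submesh(self, *regions: str) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.region_faces(*regions), process=False
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.face_region.copy(),
            dict(self.landmarks),
            dict(self.provenance),
        )

    def enclosed_volume(self, *regions: str) -> float:
        """Divergence-theorem volume of the closed surface formed by regions.

        Raises if the selected face set is not closed (has boundary edges).
        """
        faces = self.region_faces(*regions)
        if len(faces) == 0:
            raise ValueError(f"no faces in regions {regions}")
        edges = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError(f"surface formed by {regions} is not closed")
        tm = trimesh.Trimesh(vertices=self.vertices, faces=faces, process=False)
        trimesh.repair.fix_normals(tm)  # windings of separately built patches
        return abs(float(tm.volume))


@dataclass
class VolumetricMesh:
    """Labeled tetrahedral mesh with named node sets and attached fields."""

    nodes: np.ndarray
    tets: np.ndarray
    elem_tag: np.ndarray  # (n_elems,) array of str
    node_sets: dict = field(default_factory=dict)
    point_data: dict = field(default_factory=dict)
    cell_data: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.elem_tag = np.asarray(self.elem_tag)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def region_volume(self, tag: str) -> float:
        return float(self.volumes()[self.elem_tag == tag].sum())


# ---------------------------------------------------------------------------
# tetrahedron utilities


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive under the fixed ordering)."""
    p = nodes[tets]
    return np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    ) / 6.0


def fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Reorder nodes of negative-volume tets so all signed volumes are > 0."""
    tets = np.asarray(tets, dtype=np.int64).copy()
    neg = tet_volumes(nodes, tets) < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return tets


_WEDGE_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (5, 4, 3, 2, 1, 0),
    (4, 3, 5, 1, 0, 2),
]


def split_wedges(wedges: np.ndarray) -> np.ndarray:
    """Split wedges (n,6 global node ids; bottom tri then top tri, i↔i+3
    matched) into 3 tets each with conforming quad-face diagonals.

    Each quad face is split along the diagonal through its smallest global
    node id, so shared faces of adjacent wedges split identically.
    """
    wedges = np.asarray(wedges, dtype=np.int64)
    out = np.empty((len(wedges), 3, 4), dtype=np.int64)
    for n, w in enumerate(wedges):
        # relabel so the wedge's minimum global id sits at position 0
        for rot in _WEDGE_ROTATIONS:
            ww = w[list(rot)]
            if ww[0] == w.min():
                break
        i1, i2, i3, i4, i5, i6 = ww
        # third quad (i2,i3,i6,i5): diagonal through its min vertex
        if min(i2, i6) < min(i3, i5):
            tets = [(i1, i2, i3, i6), (i1, i2, i6, i5), (i1, i5, i6, i4)]
        else:
            tets = [(i1, i2, i3, i5), (i1, i5, i3, i6), (i1, i5, i6, i4)]
        out[n] = tets
    return out.reshape(-1, 4)


def extrude_wall(
    bottom: np.ndarray,
    top: np.ndarray,
    faces: np.ndarray,
    n_layers: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tetrahedralize the volume swept between two corresponded surfaces.

    ``bottom`` and ``top`` are (n,3) vertex arrays sharing the triangulation
    ``faces``; intermediate layers interpolate linearly. Returns
    ``(nodes, tets, node_layer)`` where ``node_layer[i]`` is the layer index
    (0 = bottom surface, n_layers = top surface) of node i.
    """
    bottom = np.asarray(bottom, float)
    top = np.asarray(top, float)
    faces = np.asarray(faces, np.int64)
    n = len(bottom)
    if len(top) != n:
        raise ValueError("surfaces must share the vertex grid")
    t = np.linspace(0.0, 1.0, n_layers + 1)[:, None, None]
    nodes = ((1 - t) * bottom[None] + t * top[None]).reshape(-1, 3)
    node_layer = np.repeat(np.arange(n_layers + 1), n)
    wedges = []
    for k in range(n_layers):
        lo = k * n
        hi = (k + 1) * n
        wedges.append(np.concatenate([faces + lo, faces + hi], axis=1))
    tets = split_wedges(np.concatenate(wedges))
    tets = fix_orientation(nodes, tets)
    return nodes, tets, node_layer


def merge_volumetric(parts: list[tuple[np.ndarray, np.ndarray, str]],
                     tol: float = 1e-9):
    """Merge (nodes, tets, tag) parts, deduplicating coincident nodes.

    Returns (nodes, tets, elem_tag, index_maps) where index_maps[i] maps the
    i-th part's local node ids to merged ids.
    """
    all_nodes = np.concatenate([p[0] for p in parts])
    # deduplicate by rounding to tolerance
    keys = np.round(all_nodes / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    nodes = all_nodes[first]
    offsets = np.cumsum([0] + [len(p[0]) for p in parts])
    tets_list, tags, index_maps = [], [], []
    for i, (pn, pt, tag) in enumerate(parts):
        local_map = inverse[offsets[i]: offsets[i] + len(pn)]
        index_maps.append(local_map)
        tets_list.append(local_map[pt])
        tags.extend([tag] * len(pt))
    tets = np.concatenate(tets_list)
    return nodes, tets, np.array(tags), index_maps


# ---------------------------------------------------------------------------
# point/surface predicates (vectorized; no spatial-index dependency)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances between paired points and triangles.

    ``points`` (n,3), ``tri`` (n,3,3). Region-based projection onto the
    triangle (edges/vertices handled by clamping barycentric coordinates).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (d3 >= 0) & (d4 <= d3) & ~done
    closest[m] = b[m]
    done |= m
    m = (d6 >= 0) & (d5 <= d6) & ~done
    closest[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    t = np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3), 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    t = np.where(np.abs(d2 - d6) > 1e-300, d2 / (d2 - d6), 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0) & ~done
    den = (d4 - d3) + (d5 - d6)
    t = np.where(np.abs(den) > 1e-300, (d4 - d3) / den, 0.0)
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = np.where(np.abs(va + vb + vc) > 1e-300, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(points - closest, axis=1)


def point_surface_distance(points: np.ndarray, vertices: np.ndarray,
                           faces: np.ndarray, k: int = 16) -> np.ndarray:
    """Distance from each point to a triangulated surface.

    Candidate triangles are the ``k`` with nearest centroids (plus all
    triangles incident to the nearest vertex), then the exact
    point-triangle distance is minimized.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(points)
    tri = vertices[faces]
    centroids = tri.mean(axis=1)
    k = min(k, len(faces))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand.reshape(len(points), -1))
    out = np.full(len(points), np.inf)
    for col in range(cand.shape[1]):
        d = _point_triangle_distance(points, tri[cand[:, col]])
        out = np.minimum(out, d)
    return out


def points_inside(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray,
                  chunk: int = 512) -> np.ndarray:
    """Ray-parity containment test against a closed triangulated surface.

    Casts rays along a fixed irrational direction and counts crossings
    (vectorized Möller–Trumbore over all triangles per point chunk).
    """
    points = np.atleast_2d(np.asarray(points, float))
    direction = np.array([0.5773502691896258, 0.5773502691896258 + 1e-4,
                          0.5773502691896257 - 2e-4])
    direction /= np.linalg.norm(direction)
    tri = vertices[faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    pvec = np.cross(direction, e2)  # (m,3) constant per triangle
    det = np.einsum("ij,ij->i", e1, pvec)
    valid = np.abs(det) > 1e-12
    inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
    inside = np.zeros(len(points), dtype=bool)
    for s in range(0, len(points), chunk):
        p = points[s: s + chunk]
        tvec = p[:, None, :] - v0[None]  # (c,m,3)
        u = np.einsum("cmj,mj->cm", tvec, pvec) * inv_det[None]
        qvec = np.cross(tvec, e1[None])
        v = np.einsum("cmj,j->cm", qvec, direction) * inv_det[None]
        t = np.einsum("cmj,mj->cm", qvec, e2) * inv_det[None]
        hit = (valid[None]) & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        inside[s: s + chunk] = (hit.sum(axis=1) % 2) == 1
    return inside


def surface_boundary_vertices(faces: np.ndarray) -> np.ndarray:
    """Vertex ids on the boundary (edges used by exactly one triangle)."""
    faces = np.asarray(faces, np.int64)
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])
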