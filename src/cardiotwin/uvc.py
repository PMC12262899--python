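"""Universal ventricular coordinates and rule-based fiber architecture.

UVCs parameterize positions within the ventricles by four fields: apicobasal
Z (0 at the apex, 1 on the base plane), transmural rho (0 on the
endocardium, 1 on the epicardium), rotational Phi about the long axis with
the five standard sectors (anterior, anteroseptal, inferior, inferolateral,
anterolateral), and the chamber label. Z and rho are harmonic: solutions of
the Laplace equation with Dirichlet values on the tagged boundary node sets,
discretized with linear tetrahedral finite elements.

Fibers follow a rule-based law: within each element a local orthonormal
frame (circumferential, apicobasal, transmural) is built from the gradients
of rho and Z, and the fiber direction is the circumferential axis rotated by
the helix angle alpha(rho) about the transmural axis, with the sheet tilted
by the transverse angle beta(rho). Both angles interpolate linearly across
the wall between their endocardial and epicardial limits (defaults
60° → −60° for alpha and −65° → 25° for beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .meshes import VolumetricMesh, tet_volumes

SECTORS = ("anterior", "anteroseptal", "inferior", "inferolateral",
           "anterolateral")


# ---------------------------------------------------------------------------
# linear FE Laplace


def _shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-element constant gradients of the 4 linear shape functions.

    Returns (grads (n,4,3), volumes (n,)).
    """
    p = nodes[tets]
    vol = tet_volumes(nodes, tets)
    # rows of the inverse Jacobian give gradients of barycentric coords
    e = p[:, 1:] - p[:, :1]  # (n,3,3)
    inv = np.linalg.inv(e)  # (n,3,3): columns map to gradients of l1..l3
    g123 = np.transpose(inv, (0, 2, 1))  # (n,3,3) gradient vectors in rows
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def stiffness_matrix(volmesh: VolumetricMesh) -> sparse.csr_matrix:
    grads, vol = _shape_gradients(volmesh.nodes, volmesh.tets)
    vol = np.abs(vol)
    n = volmesh.n_nodes
    ke = np.einsum("eik,ejk,e->eij", grads, grads, vol)  # (n_e,4,4)
    rows = np.repeat(volmesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(volmesh.tets, (1, 4)).reshape(-1)
    return sparse.coo_matrix((ke.reshape(-1), (rows, cols)),
                             shape=(n, n)).tocsr()


def solve_laplace(volmesh: VolumetricMesh, dirichlet: dict) -> np.ndarray:
    """Solve the Laplace equation with Dirichlet node sets.

    ``dirichlet`` maps a value to an array of node ids (or node-set name).
    The discrete solution respects the maximum principle up to solver
    tolerance.
    """
    fixed_ids, fixed_vals = [], []
    for value, ids in dirichlet.items():
        if isinstance(ids, str):
            ids = volmesh.node_sets[ids]
        ids = np.asarray(ids, dtype=np.int64)
        if len(ids) == 0:
            raise ValueError(f"empty Dirichlet set for value {value}")
        fixed_ids.append(ids)
        fixed_vals.append(np.full(len(ids), float(value)))
    fixed_ids = np.concatenate(fixed_ids)
    fixed_vals = np.concatenate(fixed_vals)
    if len(np.unique(fixed_ids)) != len(fixed_ids):
        # overlapping sets: keep first occurrence
        _, first = np.unique(fixed_ids, return_index=True)
        fixed_ids, fixed_vals = fixed_ids[first], fixed_vals[first]
    K = stiffness_matrix(volmesh)
    n = volmesh.n_nodes
    free = np.setdiff1d(np.arange(n), fixed_ids)
    u = np.zeros(n)
    u[fixed_ids] = fixed_vals
    if len(free):
        Kff = K[free][:, free].tocsc()
        rhs = -K[free][:, fixed_ids] @ fixed_vals
        try:
            u[free] = spsolve(Kff, rhs)
        except RuntimeError as err:  # singular: disconnected component
            raise ValueError(f"singular Laplace system: {err}") from err
        if not np.all(np.isfinite(u)):
            raise ValueError("Laplace solve produced non-finite values "
                             "(disconnected component without Dirichlet nodes?)")
    return u


# ---------------------------------------------------------------------------
# UVC


@dataclass
class UVC:
    z: np.ndarray  # apicobasal in [0,1]
    rho: np.ndarray  # transmural in [0,1]
    phi: np.ndarray  # rotational in (-pi, pi]
    chamber: np.ndarray  # per-node "LV"/"RV"
    sector: np.ndarray  # per-node sector name

    def as_point_data(self) -> dict:
        return {"uvc_z": self.z, "uvc_rho": self.rho, "uvc_phi": self.phi,
                "uvc_chamber": (self.chamber == "RV").astype(float)}


def compute_uvc(volmesh: VolumetricMesh, phi_reference: np.ndarray | None = None,
                sector_offset_deg: float = 0.0) -> UVC:
    """Compute (Z, rho, Phi, chamber) on a labeled ventricular mesh.

    Requires node sets ``APEX``, ``BASE``, ``LV_ENDO``/``RV_ENDO`` and
    ``LV_EPI``/``RV_EPI``. Phi is the angle about the base-centroid → apex
    axis measured from ``phi_reference`` (default: the direction from the
    long axis toward the RV centroid, i.e. through the septum), mapped to
    five equal 72° sectors.
    """
    ns = volmesh.node_sets
    for req in ("APEX", "BASE"):
        if req not in ns or len(ns[req]) == 0:
            raise ValueError(f"missing boundary node set {req}")
    z = solve_laplace(volmesh, {0.0: "APEX", 1.0: "BASE"})
    endo = np.concatenate([ns.get("LV_ENDO", []), ns.get("RV_ENDO", [])]).astype(np.int64)
    epi = np.concatenate([ns.get("LV_EPI", []), ns.get("RV_EPI", [])]).astype(np.int64)
    if len(endo) == 0 or len(epi) == 0:
        raise ValueError("missing endo/epi boundary node sets")
    rho = solve_laplace(volmesh, {0.0: endo, 1.0: epi})
    z = np.clip(z, 0.0, 1.0)
    rho = np.clip(rho, 0.0, 1.0)

    # chamber: from element tags, RV claims its nodes
    chamber = np.array(["LV"] * volmesh.n_nodes, dtype=object)
    rv_elems = np.char.startswith(volmesh.elem_tag.astype(str), "RV")
    chamber[np.unique(volmesh.tets[rv_elems])] = "RV"

    base_centroid = volmesh.nodes[ns["BASE"]].mean(axis=0)
    apex = volmesh.nodes[ns["APEX"]].mean(axis=0)
    axis = apex - base_centroid
    axis /= np.linalg.norm(axis)
    if phi_reference is None:
        rv_nodes = np.where(chamber == "RV")[0]
        target = (volmesh.nodes[rv_nodes].mean(axis=0) if len(rv_nodes)
                  else base_centroid + np.array([1.0, 0.0, 0.0]))
        ref = target - base_centroid
    else:
        ref = np.asarray(phi_reference, float)
    e1 = ref - (ref @ axis) * axis
    if np.linalg.norm(e1) < 1e-9:
        raise ValueError("phi reference direction parallel to the long axis")
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = volmesh.nodes - base_centroid
    phi = np.arctan2(rel @ e2, rel @ e1)

    bins = (np.degrees(phi) - sector_offset_deg) % 360.0
    sector = np.asarray(SECTORS)[(bins // 72).astype(int) % 5]
    return UVC(z=z, rho=rho, phi=phi, chamber=chamber.astype(str),
               sector=sector)


# ---------------------------------------------------------------------------
# fibers


@dataclass
class FiberField:
    fiber: np.ndarray  # (n_elems, 3) f
    sheet: np.ndarray  # s
    normal: np.ndarray  # n
    rho_elem: np.ndarray  # element-centroid transmural coordinate
    alpha_endo: float
    alpha_epi: float
    beta_endo: float
    beta_epi: float
    flagged: np.ndarray  # elements with degenerate gradients

    def as_cell_data(self) -> dict:
        return {"fiber": self.fiber, "sheet": self.sheet,
                "sheet_normal": self.normal, "rho_elem": self.rho_elem}


def _rotate(vectors: np.ndarray, axes: np.ndarray, angles: np.ndarray):
    """Rodrigues rotation of unit ``vectors`` about unit ``axes``."""
    c = np.cos(angles)[:, None]
    s = np.sin(angles)[:, None]
    dot = np.einsum("ij,ij->i", axes, vectors)[:, None]
    return vectors * c + np.cross(axes, vectors) * s + axes * dot * (1 - c)


def element_frames(volmesh: VolumetricMesh, uvc: UVC):
    """Local orthonormal (circumferential, longitudinal, transmural) frames.

    e_t = grad(rho)/|grad(rho)|; e_l = grad(Z) orthonormalized against e_t;
    e_c = e_l x e_t. Returns (e_c, e_l, e_t, degenerate_mask).
    """
    grads, _ = _shape_gradients(volmesh.nodes, volmesh.tets)
    g_rho = np.einsum("eik,ei->ek", grads, uvc.rho[volmesh.tets])
    g_z = np.einsum("eik,ei->ek", grads, uvc.z[volmesh.tets])
    n_rho = np.linalg.norm(g_rho, axis=1)
    n_z = np.linalg.norm(g_z, axis=1)
    bad = (n_rho < 1e-8) | (n_z < 1e-8)
    e_t = g_rho / np.maximum(n_rho, 1e-300)[:, None]
    e_l = g_z - np.einsum("ij,ij->i", g_z, e_t)[:, None] * e_t
    n_l = np.linalg.norm(e_l, axis=1)
    bad |= n_l < 1e-8
    e_l = e_l / np.maximum(n_l, 1e-300)[:, None]
    e_c = np.cross(e_l, e_t)
    return e_c, e_l, e_t, bad


def compute_fibers(volmesh: VolumetricMesh, uvc: UVC,
                   alpha_endo: float = 60.0, alpha_epi: float = -60.0,
                   beta_endo: float = -65.0, beta_epi: float = 25.0) -> FiberField:
    """Rule-based fiber/sheet/normal triads per element.

    alpha(rho) and beta(rho) interpolate linearly in the element-centroid
    transmural coordinate. Elements with degenerate gradients inherit the
    triad of the nearest valid element.
    """
    e_c, e_l, e_t, bad = element_frames(volmesh, uvc)
    rho_e = uvc.rho[volmesh.tets].mean(axis=1)
    alpha = np.deg2rad(alpha_endo + (alpha_epi - alpha_endo) * rho_e)
    beta = np.deg2rad(beta_endo + (beta_epi - beta_endo) * rho_e)
    f = _rotate(e_c, e_t, alpha)
    n0 = e_t.copy()
    s0 = np.cross(n0, f)
    s = _rotate(s0, f, beta)
    if bad.any():
        from scipy.spatial import cKDTree
        cen = volmesh.centroids()
        good = np.where(~bad)[0]
        if len(good) == 0:
            raise ValueError("all element gradients degenerate")
        _, nn = cKDTree(cen[good]).query(cen[bad])
        src = good[nn]
        f[bad], s[bad] = f[src], s[src]
    # orthonormalize (construction is orthonormal up to roundoff)
    f /= np.linalg.norm(f, axis=1)[:, None]
    s -= np.einsum("ij,ij->i", s, f)[:, None] * f
    s /= np.linalg.norm(s, axis=1)[:, None]
    n = np.cross(f, s)
    return FiberField(fiber=f, sheet=s, normal=n, rho_elem=rho_e,
                      alpha_endo=alpha_endo, alpha_epi=alpha_epi,
                      beta_endo=beta_endo, beta_epi=beta_epi, flagged=bad)


def helix_angle(fibers: FiberField, volmesh: VolumetricMesh,
                uvc: UVC) -> np.ndarray:
    """Signed angle (deg) of f projected on the (e_c, e_l) plane, from e_c.

    Elements whose fiber is (numerically) parallel to the transmural axis
    get NaN.
    """
    e_c, e_l, e_t, _ = element_frames(volmesh, uvc)
    fc = np.einsum("ij,ij->i", fibers.fiber, e_c)
    fl = np.einsum("ij,ij->i", fibers.fiber, e_l)
    out = np.degrees(np.arctan2(fl, fc))
    planar = np.hypot(fc, fl)
    out[planar < 1e-6] = np.nan
    return out


def sheet_angle(fibers: FiberField, volmesh: VolumetricMesh,
                uvc: UVC) -> np.ndarray:
    """Signed transverse angle (deg) of the sheet out of the (e_c, e_l)
    plane toward the transmural axis."""
    e_c, e_l, e_t, _ = element_frames(volmesh, uvc)
    st = np.einsum("ij,ij->i", fibers.sheet, e_t)
    sc = np.einsum("ij,ij->i", fibers.sheet, e_c)
    sl = np.einsum("ij,ij->i", fibers.sheet, e_l)
    return np.degrees(np.arctan2(st, np.hypot(sc, sl)))
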