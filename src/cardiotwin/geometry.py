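"""Analytic biventricular geometry used by the phantom and the template.

The left ventricle is a truncated prolate ellipsoid shell: the endocardial
cavity is the half-ellipsoid below the base plane z = 0 (apex pointing to
negative z), and the epicardium is the concentric ellipsoid inflated by the
wall thickness. The right ventricle is a crescent: the part of a laterally
offset ellipsoid lying outside the LV epicardium (below the base plane).
Atria are half-ellipsoid caps above the base plane and the aorta is a tube
rising from the LV base — geometric placeholders adequate for landmark
extraction, not anatomically detailed chambers.

Contraction scales cavity semi-axes by ``v**(1/3)`` so the cavity volume is
exactly ``v`` times its end-diastolic value, while the epicardium stays
fixed (the wall thickens as the cavity empties). Atria scale reciprocally
(``va = 2 - v``) so they are largest at end-systole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core_io as cio


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions (mm) of the analytic biventricular phantom geometry."""

    lv_endo_axes: tuple = (25.0, 25.0, 45.0)
    lv_wall: float = 10.0
    rv_offset: float = 30.0  # lateral (+x) shift of the RV ellipsoid center
    rv_outer_axes: tuple = (28.0, 28.0, 48.0)
    rv_wall: float = 3.0
    la_center: tuple = (-5.0, 0.0, 0.0)
    la_axes: tuple = (16.0, 16.0, 18.0)
    ra_center: tuple = (34.0, 10.0, 0.0)
    ra_axes: tuple = (14.0, 14.0, 16.0)
    ao_azimuth_deg: float = 30.0  # 3-chamber plane azimuth holding the aorta
    ao_offset: float = 14.0  # aorta axis distance from the long axis
    ao_radius: float = 6.0
    ao_height: float = 24.0

    def __post_init__(self):
        if self.lv_wall >= min(self.lv_endo_axes):
            raise ValueError("wall thickness must be below the smallest semi-axis")
        if min(self.lv_endo_axes) <= 0 or min(self.rv_outer_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def lv_epi_axes(self) -> tuple:
        return tuple(a + self.lv_wall for a in self.lv_endo_axes)

    @property
    def ao_center(self) -> np.ndarray:
        th = np.deg2rad(self.ao_azimuth_deg)
        return self.ao_offset * np.array([np.cos(th), np.sin(th), 0.0])


def _in_ellipsoid(points, center, axes):
    q = (points - np.asarray(center)) / np.asarray(axes)
    return np.einsum("ij,ij->i", q, q) <= 1.0


class PhantomGeometry:
    """Point-containment and analytic volumes for the phantom structures."""

    def __init__(self, params: GeometryParams | None = None):
        self.p = params or GeometryParams()

    # -- containment -------------------------------------------------------

    def contains(self, points, structure: str, v: float = 1.0,
                 va: float = 1.0, v_rv: float | None = None) -> np.ndarray:
        """Boolean membership of world points in a structure.

        ``v`` is the LV cavity volume fraction of its ED value (1 at ED),
        ``va`` the atrial one, ``v_rv`` the RV outer-ellipsoid one
        (defaults to ``v``; the crescent empties faster than the ellipsoid
        scales, so the generator damps it to keep RV ejection physiological).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        p = self.p
        s = v ** (1.0 / 3.0)
        sa = va ** (1.0 / 3.0)
        s_rv = (v if v_rv is None else v_rv) ** (1.0 / 3.0)
        z = points[:, 2]
        if structure == cio.LV_CAVITY:
            axes = np.asarray(p.lv_endo_axes) * s
            return _in_ellipsoid(points, (0, 0, 0), axes) & (z < 0)
        if structure == cio.LV_MYO:
            inside_epi = _in_ellipsoid(points, (0, 0, 0), p.lv_epi_axes) & (z < 0)
            return inside_epi & ~self.contains(points, cio.LV_CAVITY, v)
        if structure == cio.RV_CAVITY:
            axes = np.asarray(p.rv_outer_axes) * s_rv
            inside_outer = _in_ellipsoid(points, (p.rv_offset, 0, 0), axes)
            inside_lv_epi = _in_ellipsoid(points, (0, 0, 0), p.lv_epi_axes)
            return inside_outer & ~inside_lv_epi & (z < 0)
        if structure == cio.LA_CAVITY:
            return _in_ellipsoid(points, p.la_center, np.asarray(p.la_axes) * sa) & (z > 0)
        if structure == cio.RA_CAVITY:
            return _in_ellipsoid(points, p.ra_center, np.asarray(p.ra_axes) * sa) & (z > 0)
        if structure == cio.AORTA:
            c = p.ao_center
            r2 = (points[:, 0] - c[0]) ** 2 + (points[:, 1] - c[1]) ** 2
            return (r2 <= p.ao_radius ** 2) & (z > 0) & (z <= p.ao_height)
        raise ValueError(f"unknown structure {structure}")

    # -- volumes -----------------------------------------------------------

    def lv_cavity_volume(self, v: float = 1.0) -> float:
        """Analytic LV cavity volume (mm^3): half-ellipsoid times v."""
        a, b, c = self.p.lv_endo_axes
        return (2.0 / 3.0) * np.pi * a * b * c * v

    def lv_myo_volume(self, v: float = 1.0) -> float:
        a, b, c = self.p.lv_epi_axes
        epi = (2.0 / 3.0) * np.pi * a * b * c
        return epi - self.lv_cavity_volume(v)

    def rv_cavity_volume(self, v_rv: float = 1.0, grid_mm: float = 1.0) -> float:
        """RV crescent volume by grid quadrature (no closed form).

        ``v_rv`` is the RV outer-ellipsoid volume fraction.
        """
        p = self.p
        s = v_rv ** (1.0 / 3.0)
        ax = np.asarray(p.rv_outer_axes) * s
        lo = np.array([p.rv_offset - ax[0], -ax[1], -ax[2]])
        hi = np.array([p.rv_offset + ax[0], ax[1], 0.0])
        xs = [np.arange(lo[i], hi[i] + grid_mm, grid_mm) for i in range(3)]
        g = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = self.contains(g, cio.RV_CAVITY, v_rv=v_rv)
        return float(inside.sum()) * grid_mm ** 3

    # -- surface sampling (used by the template builder) -------------------

    def lv_ring_radius(self, z: float, surface: str, v: float = 1.0) -> float:
        """In-plane radius of the LV endo/epi surface of revolution at z."""
        if surface == "endo":
            a, _, c = np.asarray(self.p.lv_endo_axes) * v ** (1 / 3)
        else:
            a, _, c = self.p.lv_epi_axes
        if abs(z) >= c:
            return 0.0
        return a * float(np.sqrt(1.0 - (z / c) ** 2))

    def rv_cross_section(self, z: float, v: float = 1.0):
        """Crescent cross-section circles at height z.

        Returns ``(r_septum, r_fw, d, phi_sep, phi_fw)`` where ``r_septum``
        is the LV-epicardial circle radius, ``r_fw`` the RV outer circle
        radius, ``d`` the center distance and the ``phi`` values the
        half-angles subtended by the circle-circle intersection as seen from
        each center; ``None`` if the crescent is empty at z.
        """
        p = self.p
        s = v ** (1 / 3)
        a_rv, _, c_rv = np.asarray(p.rv_outer_axes) * s
        if abs(z) >= c_rv or z >= 0:
            return None
        r_fw = a_rv * float(np.sqrt(1 - (z / c_rv) ** 2))
        r_sep = self.lv_ring_radius(z, "epi")
        d = p.rv_offset
        if d >= r_sep + r_fw:  # disjoint: full RV disk, no septal arc
            return (r_sep, r_fw, d, 0.0, np.pi)
        if d + r_fw <= r_sep:  # RV swallowed by LV epi: empty crescent
            return None
        phi_fw = float(np.arccos(np.clip((d * d + r_fw * r_fw - r_sep * r_sep)
                                         / (2 * d * r_fw), -1, 1)))
        phi_sep = float(np.arccos(np.clip((d * d + r_sep * r_sep - r_fw * r_fw)
                                          / (2 * d * r_sep), -1, 1)))
        return (r_sep, r_fw, d, phi_sep, phi_fw)
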