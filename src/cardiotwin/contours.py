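"""Per-view, per-frame contour and landmark extraction from label masks.

Contours (LV endocardial, LV epicardial, RV septum, RV free wall) are traced
at half-pixel resolution as the 0.5 iso-contour of the binary mask of the
largest connected component, then lifted to world millimetres through the
series affine. Landmarks are extremal points of label-interface pixel pairs:
mitral-valve points on the LV-cavity/left-atrium interface, tricuspid points
on the RV/right-atrium interface, aortic points on the LV-cavity/aorta
interface, and the apex as the LV-epicardial contour point farthest from the
mitral midpoint. In the 3-chamber view (which carries no atrial label) the
mitral interface is the basal LV-cavity boundary against background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from . import core_io as cio
from .core_io import CineView, SegmentationSeries

# contour structure tags
LV_ENDO = "LV_ENDO"
LV_EPI = "LV_EPI"
RV_SEPTUM = "RV_SEPTUM"
RV_FW = "RV_FW"

VIEW_CONTOURS = {
    CineView.LAX2CH: (LV_ENDO, LV_EPI),
    CineView.LAX3CH: (LV_ENDO, LV_EPI, RV_SEPTUM, RV_FW),
    CineView.LAX4CH: (LV_ENDO, LV_EPI, RV_SEPTUM, RV_FW),
    CineView.SAX: (LV_ENDO, LV_EPI, RV_SEPTUM, RV_FW),
}

# landmarks per view: name -> (structure_a, structure_b); b None means
# background (used for the mitral plane in the 3-chamber view)
VIEW_LANDMARK_INTERFACES = {
    CineView.LAX2CH: {"MV": (cio.LV_CAVITY, cio.LA_CAVITY)},
    CineView.LAX3CH: {"MV": (cio.LV_CAVITY, None), "AO": (cio.LV_CAVITY, cio.AORTA)},
    CineView.LAX4CH: {"MV": (cio.LV_CAVITY, cio.LA_CAVITY),
                      "TV": (cio.RV_CAVITY, cio.RA_CAVITY)},
    CineView.SAX: {},
}


class ExtractionError(RuntimeError):
    """A required label or interface was absent; the case can be skipped."""

    def __init__(self, what: str, view: CineView, detail: str = ""):
        self.what, self.view = what, view
        super().__init__(f"{view.value}: cannot extract {what} {detail}".strip())


@dataclass
class Contour:
    structure: str
    points: np.ndarray  # (n,3) world mm
    points_px: np.ndarray  # (n,2) fractional (row,col)
    view: CineView
    frame: int
    slice_index: int = 0
    flags: list = field(default_factory=list)


@dataclass
class LandmarkSet:
    points: dict  # name -> (3,) world mm
    view: CineView
    frame: int

    def __getitem__(self, name):
        return self.points[name]

    def midpoint(self, a: str, b: str) -> np.ndarray:
        return 0.5 * (self.points[a] + self.points[b])


# ---------------------------------------------------------------------------


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected component of a binary 2D mask."""
    lab, n = measure.label(mask, connectivity=1, return_num=True)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == np.argmax(sizes)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level iso-contour of a binary mask, (n,2) (row,col)."""
    cs = measure.find_contours(mask.astype(float), 0.5)
    if not cs:
        return np.empty((0, 2))
    return max(cs, key=len)


def lift_to_3d(points2d: np.ndarray, series: SegmentationSeries,
               slice_index: int) -> np.ndarray:
    """Lift fractional (row,col) points in one slice to world mm."""
    points2d = np.atleast_2d(points2d)
    idx = np.column_stack([np.full(len(points2d), float(slice_index)), points2d])
    return cio.voxel_to_world(series, idx)


def split_rv(rv_boundary_px: np.ndarray, lv_region: np.ndarray,
             dilation_px: float = 2.0):
    """Split an RV boundary into septal and free-wall arcs.

    Boundary points within ``dilation_px`` pixels of the LV region (cavity
    plus myocardium) are septal; the rest belong to the free wall. Each part
    is returned as ordered points (order inherited from the input boundary).
    Returns ``(septum, free_wall, warnings)``.
    """
    if len(rv_boundary_px) == 0:
        raise ValueError("empty RV boundary")
    warnings = []
    if not lv_region.any():
        warnings.append("LV region empty; entire RV boundary taken as free wall")
        return np.empty((0, 2)), rv_boundary_px, warnings
    dist = ndimage.distance_transform_edt(~lv_region)
    rc = np.clip(np.round(rv_boundary_px).astype(int), 0,
                 np.array(lv_region.shape) - 1)
    near = dist[rc[:, 0], rc[:, 1]] <= dilation_px
    septum = rv_boundary_px[near]
    fw = rv_boundary_px[~near]
    if len(septum) == 0:
        warnings.append("RV boundary nowhere near LV; septum empty")
    return septum, fw, warnings


def _border_touch(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any()
                or mask[:, -1].any())


def extract_contours(frame_mask: np.ndarray, view: CineView,
                     series: SegmentationSeries, frame: int,
                     slice_index: int = 0,
                     rv_dilation_px: float = 2.0) -> list:
    """Extract the view's contours from one 2D label slice.

    ``frame_mask`` is the (row,col) label image of ``slice_index`` at
    ``frame``. Basal short-axis slices where the LV cavity touches the image
    border are rejected with an :class:`ExtractionError` (truncation guard).
    """
    scheme = series.scheme
    lv_cav = largest_component(frame_mask == scheme.label(cio.LV_CAVITY))
    if not lv_cav.any():
        raise ExtractionError(LV_ENDO, view, "(LV cavity label empty)")
    if _border_touch(lv_cav):
        raise ExtractionError(LV_ENDO, view, "(LV cavity touches image border)")
    myo = frame_mask == scheme.label(cio.LV_MYO) if cio.LV_MYO in scheme else None
    if myo is None or not myo.any():
        raise ExtractionError(LV_EPI, view, "(LV myocardium label empty)")
    lv_union = largest_component(lv_cav | myo)
    out = []

    def add(structure, pts_px, flags=()):
        if len(pts_px) < 3:
            return
        out.append(Contour(structure=structure, points_px=np.asarray(pts_px),
                           points=lift_to_3d(pts_px, series, slice_index),
                           view=view, frame=frame, slice_index=slice_index,
                           flags=list(flags)))

    add(LV_ENDO, trace_boundary(lv_cav))
    add(LV_EPI, trace_boundary(lv_union))
    wanted = VIEW_CONTOURS[view]
    if RV_SEPTUM in wanted and cio.RV_CAVITY in scheme:
        rv = largest_component(frame_mask == scheme.label(cio.RV_CAVITY))
        if rv.any():
            boundary = trace_boundary(rv)
            septum, fw, warns = split_rv(boundary, lv_union, rv_dilation_px)
            add(RV_SEPTUM, septum, warns)
            add(RV_FW, fw, warns)
    return out


def interface_points(frame_mask: np.ndarray, label_a: int,
                     label_b: int | None) -> np.ndarray:
    """Midpoints of 4-adjacent pixel pairs between two labels.

    ``label_b=None`` means background (0). Returns (n,2) fractional
    (row,col) points located between the paired pixel centers.
    """
    a = frame_mask == label_a
    b = (frame_mask == 0) if label_b is None else (frame_mask == label_b)
    pts = []
    for axis in (0, 1):
        n = a.shape[axis]
        lo = slice(0, n - 1)
        hi = slice(1, n)
        for x, y in ((a, b), (b, a)):
            x_lo = x.take(range(0, n - 1), axis=axis)
            y_hi = y.take(range(1, n), axis=axis)
            rr, cc = np.nonzero(x_lo & y_hi)
            mid = np.column_stack([rr.astype(float), cc.astype(float)])
            mid[:, axis] += 0.5
            pts.append(mid)
    pts = np.concatenate(pts) if pts else np.empty((0, 2))
    return np.unique(pts, axis=0) if len(pts) else pts


def _extremal_pair(points: np.ndarray):
    """The two extremal points along the principal direction of a point set."""
    c = points.mean(axis=0)
    d = points - c
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    proj = d @ vt[0]
    return points[np.argmin(proj)], points[np.argmax(proj)]


def extract_landmarks(frame_mask: np.ndarray, view: CineView,
                      series: SegmentationSeries, frame: int,
                      slice_index: int = 0) -> LandmarkSet:
    """Named anatomical landmarks of one long-axis slice, in world mm."""
    scheme = series.scheme
    named = {}
    for name, (sa, sb) in VIEW_LANDMARK_INTERFACES[view].items():
        if sa not in scheme or (sb is not None and sb not in scheme):
            raise ExtractionError(name, view, "(required labels not in scheme)")
        la = scheme.label(sa)
        lb = None if sb is None else scheme.label(sb)
        pts = interface_points(frame_mask, la, lb)
        if name == "MV" and sb is None:
            # 3-chamber: exclude the aortic part of the basal opening
            ao = interface_points(frame_mask, la, scheme.label(cio.AORTA))
            if len(ao) and len(pts):
                from scipy.spatial import cKDTree
                d, _ = cKDTree(ao).query(pts)
                pts = pts[d > 1.5]
        if len(pts) < 2:
            raise ExtractionError(name, view, f"({sa}|{sb or 'background'} "
                                              "interface empty)")
        p1, p2 = _extremal_pair(pts)
        named[f"{name}_1"], named[f"{name}_2"] = p1, p2
    points = {k: lift_to_3d(v, series, slice_index)[0] for k, v in named.items()}
    if "MV_1" in points and view is CineView.LAX2CH:
        # apex: farthest LV-epicardial contour point from the mitral midpoint
        myo = frame_mask == scheme.label(cio.LV_MYO)
        lv = frame_mask == scheme.label(cio.LV_CAVITY)
        epi_px = trace_boundary(largest_component(lv | myo))
        if len(epi_px) == 0:
            raise ExtractionError("APEX", view, "(no epicardial contour)")
        epi = lift_to_3d(epi_px, series, slice_index)
        mid = 0.5 * (points["MV_1"] + points["MV_2"])
        points["APEX"] = epi[np.argmax(np.linalg.norm(epi - mid, axis=1))]
    bad = [k for k, v in points.items() if not np.all(np.isfinite(v))]
    if bad:
        raise ExtractionError(",".join(bad), view, "(non-finite landmark)")
    return LandmarkSet(points=points, view=view, frame=frame)


def extract_view(series: SegmentationSeries, frame: int,
                 rv_dilation_px: float = 2.0):
    """All contours (every usable slice) and landmarks of a view at a frame.

    Returns ``(contours, landmarks_or_None, skipped_slices)``; short-axis
    slices failing the truncation guard or lacking labels are skipped and
    reported rather than fatal.
    """
    contours, skipped = [], []
    for s in range(series.n_slices):
        mask = series.data[s, :, :, frame]
        try:
            contours.extend(extract_contours(mask, series.view, series, frame,
                                             slice_index=s,
                                             rv_dilation_px=rv_dilation_px))
        except ExtractionError as err:
            skipped.append((s, str(err)))
    landmarks = None
    if VIEW_LANDMARK_INTERFACES[series.view]:
        landmarks = extract_landmarks(series.data[0, :, :, frame], series.view,
                                      series, frame, slice_index=0)
    if not contours:
        raise ExtractionError("all contours", series.view,
                              f"(no usable slices: {skipped})")
    return contours, landmarks, skipped
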