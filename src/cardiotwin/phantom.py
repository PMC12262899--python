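"""Seeded synthetic 4-view cine segmentation bundles with known ground truth.

The phantom stands in for restricted population imaging data: it rasterizes
the analytic biventricular geometry of :mod:`cardiotwin.geometry` into the
four standard cine views (a short-axis stack plus 2-/3-/4-chamber long-axis
planes), each through its own voxel-to-world affine, with the acquisition
geometry of a typical population cine protocol (1.8x1.8x8 mm short axis,
1.6x1.6x6 mm long axis, 50 time frames). Cavity volumes follow a smooth
cosine transient dipping to ``es_volume_fraction`` at ``es_frame``, so the
true end-systolic frame, per-frame volumes and surfaces are known exactly.
Breath-hold slice misalignment is emulated by seeded in-plane shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import core_io as cio
from .core_io import CineView, DEFAULT_SCHEMES, SegmentationSeries, StudyBundle
from .geometry import GeometryParams, PhantomGeometry

# rasterization priority: first containing structure wins where placeholders
# overlap (the aorta root sits against the LA cap)
_PRIORITY = (cio.LV_CAVITY, cio.LV_MYO, cio.RV_CAVITY, cio.AORTA,
             cio.LA_CAVITY, cio.RA_CAVITY)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, transient and acquisition parameters of one phantom."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    n_frames: int = 50
    es_frame: int = 18
    es_volume_fraction: float = 0.4
    n_sax_slices: int = 10
    sax_inplane: float = 1.8  # mm
    sax_gap: float = 8.0  # mm slice spacing
    lax_inplane: float = 1.6  # mm
    lax_thickness: float = 6.0  # mm
    grid_size: int = 64  # in-plane matrix size for all views
    misalignment_sd: float = 0.0  # mm
    rv_damping: float = 0.6  # damps the RV transient toward normal RV EF
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.es_frame < self.n_frames:
            raise ValueError("es_frame must lie strictly inside the cycle")
        if not 0 < self.es_volume_fraction < 1:
            raise ValueError("es_volume_fraction must be in (0,1)")
        if self.misalignment_sd < 0:
            raise ValueError("misalignment_sd must be >= 0")


@dataclass
class PhantomStudy:
    """A phantom bundle plus its analytic ground truth."""

    bundle: StudyBundle
    params: PhantomParams
    lv_cavity_ml: np.ndarray  # per-frame true LV cavity volume
    rv_cavity_ml: np.ndarray
    lv_myo_ml: np.ndarray
    es_frame: int
    shifts: dict  # applied misalignment, see apply_misalignment
    geometry: PhantomGeometry


def volume_transient(n_frames: int, es_frame: int, es_fraction: float) -> np.ndarray:
    """Cosine-based cavity volume fraction: 1 at frame 0, minimum at ES."""
    t = np.arange(n_frames, dtype=float)
    w = np.empty(n_frames)
    down = t <= es_frame
    w[down] = 0.5 * (1 - np.cos(np.pi * t[down] / es_frame))
    rest = n_frames - 1 - es_frame
    if rest > 0:
        w[~down] = 0.5 * (1 - np.cos(np.pi * (n_frames - 1 - t[~down]) / rest))
    return 1.0 - (1.0 - es_fraction) * w


def _view_affine(params: PhantomParams, view: CineView) -> tuple:
    """(affine, shape) for a view; index order (slice,row,col)."""
    p = params
    if view is CineView.SAX:
        n = p.grid_size
        aff = np.eye(4)
        aff[:3, 0] = (0, 0, p.sax_gap)  # slice axis along +z
        aff[:3, 1] = (0, p.sax_inplane, 0)  # rows along +y
        aff[:3, 2] = (p.sax_inplane, 0, 0)  # cols along +x
        aff[:3, 3] = (10 - p.sax_inplane * (n - 1) / 2,
                      -p.sax_inplane * (n - 1) / 2, -58.0)
        return aff, (p.n_sax_slices, n, n)
    # long-axis planes all contain the long (z) axis
    th = {CineView.LAX4CH: 0.0,
          CineView.LAX2CH: np.pi / 2,
          CineView.LAX3CH: np.deg2rad(30.0)}[view]
    e_t = np.array([np.cos(th), np.sin(th), 0.0])  # in-plane transverse
    normal = np.array([-np.sin(th), np.cos(th), 0.0])
    n = p.grid_size
    aff = np.eye(4)
    aff[:3, 0] = normal * p.lax_thickness
    aff[:3, 1] = (0, 0, p.lax_inplane)  # rows along +z
    aff[:3, 2] = e_t * p.lax_inplane
    aff[:3, 3] = e_t * (7.5 - p.lax_inplane * (n - 1) / 2) + np.array([0, 0, -60.0])
    return aff, (1, n, n)


def rasterize_view(geometry: PhantomGeometry, view: CineView, affine: np.ndarray,
                   shape: tuple, v: float = 1.0, va: float = 1.0,
                   v_rv: float | None = None, scheme=None) -> np.ndarray:
    """Label each voxel by the structure containing its world-space center."""
    scheme = scheme or DEFAULT_SCHEMES[view]
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3).astype(float)
    pts = (affine[:3, :3] @ idx.T + affine[:3, 3:4]).T
    labels = np.zeros(len(pts), dtype=np.int16)
    for structure in _PRIORITY:
        if structure not in scheme:
            continue
        hit = geometry.contains(pts, structure, v=v, va=va, v_rv=v_rv) \
            & (labels == 0)
        labels[hit] = scheme.label(structure)
    return labels.reshape(shape)


def make_phantom(params: PhantomParams | None = None,
                 participant_id: str = "phantom",
                 demographics: cio.Demographics | None = None) -> PhantomStudy:
    """Generate one synthetic 4-view study with analytic ground truth."""
    params = params or PhantomParams()
    geom = PhantomGeometry(params.geometry)
    v = volume_transient(params.n_frames, params.es_frame, params.es_volume_fraction)
    va = 2.0 - v
    v_rv = 1.0 - params.rv_damping * (1.0 - v)
    series = {}
    for view in CineView:
        aff, shape = _view_affine(params, view)
        frames = [rasterize_view(geom, view, aff, shape, v=v[t], va=va[t],
                                 v_rv=v_rv[t])
                  for t in range(params.n_frames)]
        series[view] = SegmentationSeries(
            data=np.stack(frames, axis=-1), affine=aff,
            scheme=DEFAULT_SCHEMES[view], view=view)
    bundle = StudyBundle(participant_id=participant_id, series=series,
                         demographics=demographics)
    lv_ml = np.array([geom.lv_cavity_volume(vi) for vi in v]) / 1000.0
    myo_ml = np.array([geom.lv_myo_volume(vi) for vi in v]) / 1000.0
    rv_ml = np.array([geom.rv_cavity_volume(vi, grid_mm=1.5)
                      for vi in v_rv]) / 1000.0
    study = PhantomStudy(bundle=bundle, params=params, lv_cavity_ml=lv_ml,
                         rv_cavity_ml=rv_ml, lv_myo_ml=myo_ml,
                         es_frame=params.es_frame, shifts={}, geometry=geom)
    if params.misalignment_sd > 0:
        study.bundle, study.shifts = apply_misalignment(
            bundle, params.misalignment_sd, params.seed)
    return study


def apply_misalignment(bundle: StudyBundle, sd: float, seed: int):
    """Translate each SAX slice and each LAX view in-plane by seeded shifts.

    Shifts are zero-mean normal with standard deviation ``sd`` (mm) per
    in-plane axis, constant over the cycle (breath-hold per acquisition).
    Labels are resampled nearest-neighbor. Returns the shifted bundle and a
    dict ``{(view, slice): (d_row_mm, d_col_mm)}`` of applied shifts.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return bundle, {}
    rng = np.random.default_rng(seed)
    shifts = {}
    new_series = {}
    for view in sorted(bundle.series, key=lambda v: v.value):
        series = bundle.series[view]
        data = series.data.copy()
        sp = series.spacing  # (slice,row,col) mm
        if view is CineView.SAX:
            for s in range(series.n_slices):
                d = rng.normal(0.0, sd, size=2)  # (row, col) mm
                shifts[(view.value, s)] = tuple(d)
                px = (d[0] / sp[1], d[1] / sp[2])
                for t in range(series.n_frames):
                    data[s, :, :, t] = ndimage.shift(
                        data[s, :, :, t], px, order=0, mode="constant", cval=0)
        else:
            d = rng.normal(0.0, sd, size=2)
            shifts[(view.value, 0)] = tuple(d)
            px = (d[0] / sp[1], d[1] / sp[2])
            for t in range(series.n_frames):
                data[0, :, :, t] = ndimage.shift(
                    data[0, :, :, t], px, order=0, mode="constant", cval=0)
        new_series[view] = SegmentationSeries(data=data, affine=series.affine,
                                              scheme=series.scheme, view=view)
    return StudyBundle(bundle.participant_id, new_series, bundle.demographics), shifts


def random_phantom_params(rng: np.random.Generator,
                          base: PhantomParams | None = None,
                          n_frames: int | None = None) -> PhantomParams:
    """Seeded anatomical variation: semi-axes within ~±15%, varying ES."""
    base = base or PhantomParams()
    g = base.geometry
    scale = rng.uniform(0.85, 1.15, size=3)
    lv = tuple(np.asarray(g.lv_endo_axes) * scale)
    rv = tuple(np.asarray(g.rv_outer_axes) * rng.uniform(0.85, 1.15, size=3))
    wall = g.lv_wall * rng.uniform(0.85, 1.15)
    nf = n_frames or base.n_frames
    es = int(rng.integers(max(1, nf * 3 // 10), max(2, nf * 6 // 10)))
    frac = float(rng.uniform(0.3, 0.5))
    geom = replace(g, lv_endo_axes=lv, rv_outer_axes=rv, lv_wall=wall)
    return replace(base, geometry=geom, n_frames=nf, es_frame=es,
                   es_volume_fraction=frac, seed=int(rng.integers(2**31 - 1)))


def random_demographics(rng: np.random.Generator) -> cio.Demographics:
    return cio.Demographics(
        sex="F" if rng.random() < 0.5 else "M",
        age=float(rng.uniform(44, 86)),
        bmi=float(rng.uniform(17, 40)),
    )


def write_phantom(study: PhantomStudy, outdir) -> None:
    """Write a phantom bundle as NIfTI files plus a ground-truth JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for view, series in study.bundle.series.items():
        cio.write_segmentation_series(series, outdir / f"{view.value}.nii.gz")
    truth = {
        "es_frame": int(study.es_frame),
        "lv_cavity_ml": study.lv_cavity_ml.tolist(),
        "rv_cavity_ml": study.rv_cavity_ml.tolist(),
        "lv_myo_ml": study.lv_myo_ml.tolist(),
        "shifts": {f"{k[0]}:{k[1]}": list(map(float, v))
                   for k, v in study.shifts.items()},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
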