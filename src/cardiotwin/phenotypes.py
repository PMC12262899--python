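"""Cardiac phenotypes from segmentations (voxel summation) and meshes
(divergence-theorem volume), plus ejection fraction, LV mass, atrial
volumes and the Dice overlap metric.

Two routes to the same physiology deliberately coexist: segmentation-derived
volumes are voxel counts times voxel volume on the short-axis stack, while
mesh-derived volumes integrate the fitted closed surfaces. Their agreement
is the basis of the cohort quality-control rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import core_io as cio
from . import surface as sf
from .core_io import CineView, SegmentationSeries, StudyBundle
from .meshes import SurfaceMesh

MYO_DENSITY_G_PER_ML = 1.05


@dataclass
class PhenotypeRecord:
    participant_id: str
    source: str  # "SEGMENTATION" or "MESH"
    lvedv: float  # mL
    lvesv: float
    rvedv: float
    rvesv: float
    lvm: float  # g
    lvef: float  # %
    rvef: float
    la_min: float | None = None
    la_max: float | None = None
    ra_min: float | None = None
    ra_max: float | None = None

    def __post_init__(self):
        for name in ("lvedv", "lvesv", "rvedv", "rvesv", "lvm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def seg_volumes(series: SegmentationSeries, frame: int, structure: str) -> float:
    """Structure volume (mL) at one frame: voxel count x voxel volume."""
    if structure not in series.scheme:
        raise ValueError(f"{structure} not in scheme")
    if not 0 <= frame < series.n_frames:
        raise IndexError(f"frame {frame} out of range")
    count = int((series.data[..., frame] == series.scheme.label(structure)).sum())
    return count * series.voxel_volume / 1000.0


def lv_mass(myo_volume_ml: float, density: float = MYO_DENSITY_G_PER_ML) -> float:
    """LV mass (g) from end-diastolic myocardial volume at 1.05 g/mL."""
    if myo_volume_ml < 0:
        raise ValueError("myocardial volume must be >= 0")
    return density * myo_volume_ml


def mesh_volumes(surface: SurfaceMesh) -> dict:
    """Cavity and myocardial volumes (mL) of a fitted, capped surface.

    LV cavity closes with the mitral/aortic lids, the epicardial envelope
    with the basal lid; LV myocardial volume is their difference (valve lids
    are surfaces here and carry no volume). RV cavity closes with the
    tricuspid/pulmonary lids.
    """
    lv_cav = surface.enclosed_volume(sf.LV_ENDO_S, sf.MV_RING, sf.AO_RING)
    epi = surface.enclosed_volume(sf.LV_EPI_S, sf.BASE_LID)
    rv_cav = surface.enclosed_volume(sf.RV_SEPTUM_S, sf.RV_FW_S,
                                     sf.TV_RING, sf.PV_RING)
    return {"lv_cavity": lv_cav / 1000.0,
            "rv_cavity": rv_cav / 1000.0,
            "lv_myo": (epi - lv_cav) / 1000.0}


def ejection_fraction(edv: float, esv: float) -> float:
    """EF (%) = 100 (EDV - ESV) / EDV; ESV > EDV clamps to 0 with a warning."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if esv > edv:
        warnings.warn("ESV exceeds EDV; clamping ejection fraction to 0")
        return 0.0
    return 100.0 * (edv - esv) / edv


def _area_length(series: SegmentationSeries, structure: str, partner: str,
                 frame: int):
    """(area mm^2, length mm) of an atrial cap in one long-axis frame.

    Length runs from the valve-plane interface midpoint to the farthest
    atrial voxel center.
    """
    from .contours import interface_points, lift_to_3d

    mask2d = series.data[0, :, :, frame]
    atrium = mask2d == series.scheme.label(structure)
    if not atrium.any():
        return None
    pix_area = series.spacing[1] * series.spacing[2]
    area = float(atrium.sum()) * pix_area
    iface = interface_points(mask2d, series.scheme.label(partner),
                             series.scheme.label(structure))
    if len(iface) == 0:
        return None
    mid = lift_to_3d(iface.mean(axis=0), series, 0)[0]
    rr, cc = np.nonzero(atrium)
    pts = lift_to_3d(np.column_stack([rr, cc]).astype(float), series, 0)
    length = float(np.linalg.norm(pts - mid, axis=1).max())
    if length <= 0:
        return None
    return area, length


def atrial_volumes(bundle: StudyBundle, frames=None) -> dict:
    """Min/max atrial volumes (mL) over the cycle by area-length.

    LA uses the biplane area-length rule V = (8/(3 pi)) A2 A4 / L with the
    2- and 4-chamber areas and the shorter of the two lengths; RA uses the
    single-plane rule V = (8/(3 pi)) A^2 / L on the 4-chamber view. Frames
    where a chamber is empty are skipped with a warning.
    """
    two = bundle.get(CineView.LAX2CH)
    four = bundle.get(CineView.LAX4CH)
    if four is None or cio.RA_CAVITY not in four.scheme:
        raise ValueError("RA volumes need a 4-chamber view with an RA label")
    if two is None or cio.LA_CAVITY not in two.scheme:
        raise ValueError("LA volumes need a 2-chamber view with an LA label")
    if frames is None:
        frames = range(min(two.n_frames, four.n_frames))
    la, ra = [], []
    skipped = []
    for t in frames:
        a2 = _area_length(two, cio.LA_CAVITY, cio.LV_CAVITY, t)
        a4 = _area_length(four, cio.LA_CAVITY, cio.LV_CAVITY, t)
        if a2 and a4:
            la.append((8.0 / (3.0 * np.pi)) * a2[0] * a4[0]
                      / min(a2[1], a4[1]) / 1000.0)
        else:
            skipped.append(t)
        r4 = _area_length(four, cio.RA_CAVITY, cio.RV_CAVITY, t)
        if r4:
            ra.append((8.0 / (3.0 * np.pi)) * r4[0] ** 2 / r4[1] / 1000.0)
    if skipped:
        warnings.warn(f"atrial volumes skipped empty frames {skipped}")
    if not la or not ra:
        raise ValueError("no frame with usable atrial labels")
    return {"la_min": float(np.min(la)), "la_max": float(np.max(la)),
            "ra_min": float(np.min(ra)), "ra_max": float(np.max(ra))}


def dice(mask_a: np.ndarray, mask_b: np.ndarray, label: int) -> float:
    """Dice overlap of one label between two arrays; Dice(empty, empty) = 1."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch {mask_a.shape} vs {mask_b.shape}")
    a = mask_a == label
    b = mask_b == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def seg_phenotypes(bundle: StudyBundle, ed: int, es: int) -> PhenotypeRecord:
    """Segmentation-derived phenotypes from the short-axis stack."""
    sax = bundle.get(CineView.SAX)
    if sax is None:
        raise ValueError("segmentation phenotypes need the SAX view")
    lvedv = seg_volumes(sax, ed, cio.LV_CAVITY)
    lvesv = seg_volumes(sax, es, cio.LV_CAVITY)
    rvedv = seg_volumes(sax, ed, cio.RV_CAVITY)
    rvesv = seg_volumes(sax, es, cio.RV_CAVITY)
    lvm = lv_mass(seg_volumes(sax, ed, cio.LV_MYO))
    rec = PhenotypeRecord(
        participant_id=bundle.participant_id, source="SEGMENTATION",
        lvedv=lvedv, lvesv=lvesv, rvedv=rvedv, rvesv=rvesv, lvm=lvm,
        lvef=ejection_fraction(lvedv, lvesv),
        rvef=ejection_fraction(rvedv, rvesv))
    try:
        rec.__dict__.update(atrial_volumes(bundle))
    except ValueError:
        pass
    return rec


def mesh_phenotypes(participant_id: str, surface_ed: SurfaceMesh,
                    surface_es: SurfaceMesh) -> PhenotypeRecord:
    """Mesh-derived phenotypes from fitted ED and ES surfaces."""
    ved = mesh_volumes(surface_ed)
    ves = mesh_volumes(surface_es)
    return PhenotypeRecord(
        participant_id=participant_id, source="MESH",
        lvedv=ved["lv_cavity"], lvesv=ves["lv_cavity"],
        rvedv=ved["rv_cavity"], rvesv=ves["rv_cavity"],
        lvm=lv_mass(ved["lv_myo"]),
        lvef=ejection_fraction(ved["lv_cavity"], ves["lv_cavity"]),
        rvef=ejection_fraction(ved["rv_cavity"], ves["rv_cavity"]))
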