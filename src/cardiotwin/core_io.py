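"""Domain types and I/O shared by every pipeline stage.

Conventions (fixed across the package):

* label arrays are indexed ``(slice, row, col, time)``; long-axis views carry
  a singleton slice axis so all views share one container;
* all geometry is expressed in world millimetres through the NIfTI affine,
  which maps 0-based integer voxel centers to world coordinates;
* label schemes are per-view configuration defaulting to the per-view
  structure lists used for cine CMR segmentation (the 3-chamber view is the
  only one that includes the aorta); unknown labels are an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

from .meshes import SurfaceMesh, VolumetricMesh

# structure names
LV_CAVITY = "LV_CAVITY"
LV_MYO = "LV_MYO"
RV_CAVITY = "RV_CAVITY"
LA_CAVITY = "LA_CAVITY"
RA_CAVITY = "RA_CAVITY"
AORTA = "AORTA"

STRUCTURES = (LV_CAVITY, LV_MYO, RV_CAVITY, LA_CAVITY, RA_CAVITY, AORTA)


class CineView(str, Enum):
    """The four cine CMR views the pipeline consumes."""

    LAX2CH = "LAX2CH"
    LAX3CH = "LAX3CH"
    LAX4CH = "LAX4CH"
    SAX = "SAX"


@dataclass(frozen=True)
class LabelScheme:
    """Mapping structure name -> positive integer label (0 is background)."""

    labels: dict

    def __post_init__(self):
        vals = list(self.labels.values())
        if len(set(vals)) != len(vals):
            raise ValueError("labels must be unique within a scheme")
        if any(v <= 0 for v in vals):
            raise ValueError("labels must be positive (0 is background)")
        unknown = set(self.labels) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")

    def __contains__(self, structure: str) -> bool:
        return structure in self.labels

    def label(self, structure: str) -> int:
        return self.labels[structure]

    def valid_values(self) -> set:
        return set(self.labels.values()) | {0}


DEFAULT_SCHEMES = {
    CineView.LAX2CH: LabelScheme({LV_CAVITY: 1, LV_MYO: 2, LA_CAVITY: 3}),
    CineView.LAX3CH: LabelScheme(
        {LV_CAVITY: 1, LV_MYO: 2, RV_CAVITY: 3, RA_CAVITY: 4, AORTA: 5}
    ),
    CineView.LAX4CH: LabelScheme(
        {LV_CAVITY: 1, LV_MYO: 2, RV_CAVITY: 3, LA_CAVITY: 4, RA_CAVITY: 5}
    ),
    CineView.SAX: LabelScheme({LV_CAVITY: 1, LV_MYO: 2, RV_CAVITY: 3}),
}


def load_schemes(path) -> dict:
    """Load per-view label schemes from a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {CineView(k): LabelScheme(v) for k, v in raw.items()}


@dataclass
class SegmentationSeries:
    """One view's label volume over time plus its voxel-to-world affine."""

    data: np.ndarray  # (slice, row, col, time) integer labels
    affine: np.ndarray  # 4x4, maps (slice, row, col) voxel centers to mm
    scheme: LabelScheme
    view: CineView

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError("data must be (slice,row,col,time)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def spacing(self) -> tuple:
        """mm per (slice, row, col) step, from the affine column norms."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel (parallelepiped spanned by the affine columns)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def validate_labels(self) -> list:
        present = set(np.unique(self.data).tolist())
        bad = sorted(present - self.scheme.valid_values())
        return bad

    def mask(self, structure: str, frame: int) -> np.ndarray:
        """Binary (slice,row,col) mask of a structure at one frame."""
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} out of range [0,{self.n_frames})")
        return self.data[..., frame] == self.scheme.label(structure)


@dataclass(frozen=True)
class Demographics:
    sex: str  # "F" or "M"
    age: float  # years
    bmi: float  # kg/m^2

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if not self.age > 0 or not self.bmi > 0:
            raise ValueError("age and bmi must be positive")


@dataclass
class StudyBundle:
    """One participant's per-view segmentations plus demographics."""

    participant_id: str
    series: dict  # CineView -> SegmentationSeries
    demographics: Demographics | None = None

    def get(self, view: CineView) -> SegmentationSeries | None:
        return self.series.get(view)

    @property
    def views(self) -> list:
        return sorted(self.series, key=lambda v: v.value)


# ---------------------------------------------------------------------------
# segmentation I/O


def read_segmentation_series(path, scheme: LabelScheme,
                             view: CineView) -> SegmentationSeries:
    """Read a NIfTI label map as a segmentation time series.

    The affine is taken from the file header; data must be integer-valued and
    all labels must belong to the scheme (plus background 0).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: segmentation data is not integer-valued")
        data = rounded.astype(np.int16)
    series = SegmentationSeries(data=data, affine=img.affine, scheme=scheme, view=view)
    bad = series.validate_labels()
    if bad:
        raise ValueError(f"{path}: labels outside scheme: {bad}")
    return series


def write_segmentation_series(series: SegmentationSeries, path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.int16), series.affine)
    nib.save(img, str(path))


def voxel_to_world(series: SegmentationSeries, index) -> np.ndarray:
    """Map (slice,row,col) voxel index (fractional allowed) to world mm."""
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    shape = series.data.shape[:3]
    if np.any(idx < -0.5) or np.any(idx > np.asarray(shape) - 0.5):
        raise IndexError(f"index {index} outside array bounds {shape}")
    pts = series.affine[:3, :3] @ idx.T + series.affine[:3, 3:4]
    out = pts.T
    return out[0] if np.ndim(index) == 1 else out


def world_to_voxel(series: SegmentationSeries, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(series.affine)
    idx = inv[:3, :3] @ pts.T + inv[:3, 3:4]
    out = idx.T
    return out[0] if np.ndim(points) == 1 else out


# ---------------------------------------------------------------------------
# bundle validation


@dataclass(frozen=True)
class Issue:
    code: str
    detail: str

    def __str__(self):
        return f"{self.code}({self.detail})"


def validate_bundle(bundle: StudyBundle,
                    required_views=tuple(CineView)) -> list:
    """Check a bundle for missing views, bad labels and frame-count mismatch.

    Issues are data, not exceptions; an empty report means the bundle is
    ready for meshing.
    """
    report = []
    for view in required_views:
        if bundle.get(view) is None:
            report.append(Issue("MISSING_VIEW", view.value))
    frame_counts = {}
    for view, series in bundle.series.items():
        bad = series.validate_labels()
        if bad:
            report.append(Issue("BAD_LABELS", f"{view.value}:{bad}"))
        frame_counts[view.value] = series.n_frames
    if len(set(frame_counts.values())) > 1:
        report.append(Issue("FRAME_MISMATCH", json.dumps(frame_counts)))
    return report


# ---------------------------------------------------------------------------
# mesh I/O: legacy-VTK ASCII plus a CARP-style .pts/.elem/.lon text dialect

_VTK_TRI = 5
_VTK_TET = 10


def _write_fields(fh, n, data: dict, kind: str):
    if not data:
        return
    fh.write(f"{kind} {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.17g")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.astype(float), fmt="%.17g")


def write_mesh(mesh, path, fmt: str = "vtk") -> None:
    """Write a surface or volumetric mesh.

    ``fmt='vtk'`` writes a legacy-VTK ASCII unstructured grid readable by
    standard mesh tooling, with region tags, UVC fields and fiber vectors as
    named point/cell data plus a JSON sidecar (``<path>.json``) holding the
    string region names, landmarks and node sets. ``fmt='carp'`` writes the
    plain-text ``.pts``/``.elem`` (and ``.lon`` for fibers) element/node
    dialect used by cardiac simulation tools.
    """
    path = Path(path)
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "carp":
        _write_carp(mesh, path)
    else:
        raise ValueError(f"unsupported format: {fmt}")


def _tag_codes(tags: np.ndarray):
    names = sorted(set(tags.tolist()))
    code = {t: i + 1 for i, t in enumerate(names)}
    return names, np.array([code[t] for t in tags])


def _write_vtk(mesh, path: Path) -> None:
    is_surface = isinstance(mesh, SurfaceMesh)
    if is_surface:
        points, cells = mesh.vertices, mesh.faces
        tags = mesh.face_region
        cell_data, point_data = {}, {}
        sidecar = {"landmarks": {k: int(v) for k, v in mesh.landmarks.items()}}
    elif isinstance(mesh, VolumetricMesh):
        points, cells = mesh.nodes, mesh.tets
        tags = mesh.elem_tag
        cell_data = dict(mesh.cell_data)
        point_data = dict(mesh.point_data)
        sidecar = {"node_sets": {k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()}}
    else:
        raise TypeError(f"cannot write {type(mesh)}")
    names, codes = _tag_codes(tags)
    sidecar["region_names"] = names
    ctype = _VTK_TRI if is_surface else _VTK_TET
    npc = cells.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardiotwin mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.17g")
        fh.write(f"CELLS {len(cells)} {len(cells) * (npc + 1)}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(cells), npc), cells]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), ctype), fmt="%d")
        all_cell = {"region": codes, **cell_data}
        _write_fields(fh, len(cells), all_cell, "CELL_DATA")
        _write_fields(fh, len(points), point_data, "POINT_DATA")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_mesh(path):
    """Read back a mesh written by :func:`write_mesh` (vtk format)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def seek(prefix):
        nonlocal i
        while not lines[i].startswith(prefix):
            i += 1
        return lines[i]

    header = seek("POINTS").split()
    n_pts = int(header[1])
    points = np.loadtxt(lines[i + 1: i + 1 + n_pts]).reshape(n_pts, 3)
    i += 1 + n_pts
    header = seek("CELLS").split()
    n_cells = int(header[1])
    raw = np.loadtxt(lines[i + 1: i + 1 + n_cells], dtype=np.int64).reshape(n_cells, -1)
    cells = raw[:, 1:]
    i += 1 + n_cells
    seek("CELL_TYPES")
    ctype = int(lines[i + 1])
    fields = {"cell": {}, "point": {}}
    mode = None
    j = i + 1 + n_cells
    count = 0
    while j < len(lines):
        ln = lines[j]
        if ln.startswith("CELL_DATA"):
            mode, count = "cell", int(ln.split()[1])
            j += 1
        elif ln.startswith("POINT_DATA"):
            mode, count = "point", int(ln.split()[1])
            j += 1
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            j += 2  # skip LOOKUP_TABLE
            fields[mode][name] = np.loadtxt(lines[j: j + count])
            j += count
        elif ln.startswith("VECTORS"):
            name = ln.split()[1]
            j += 1
            fields[mode][name] = np.loadtxt(lines[j: j + count]).reshape(count, 3)
            j += count
        else:
            j += 1
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    names = sidecar.get("region_names", [])
    codes = fields["cell"].pop("region").astype(int)
    tags = np.array([names[c - 1] if names else str(c) for c in codes])
    if ctype == _VTK_TRI:
        return SurfaceMesh(
            points, cells, tags,
            landmarks={k: int(v) for k, v in sidecar.get("landmarks", {}).items()},
        )
    return VolumetricMesh(
        points, cells, tags,
        node_sets={k: np.asarray(v, dtype=np.int64)
                   for k, v in sidecar.get("node_sets", {}).items()},
        point_data=fields["point"],
        cell_data=fields["cell"],
    )


def _write_carp(mesh, path: Path) -> None:
    base = path.with_suffix("")
    if isinstance(mesh, SurfaceMesh):
        points, cells, tags, kind = mesh.vertices, mesh.faces, mesh.face_region, "Tr"
    else:
        points, cells, tags, kind = mesh.nodes, mesh.tets, mesh.elem_tag, "Tt"
    _, codes = _tag_codes(tags)
    with open(base.with_suffix(".pts"), "w") as fh:
        fh.write(f"{len(points)}\n")
        np.savetxt(fh, points, fmt="%.17g")
    with open(base.with_suffix(".elem"), "w") as fh:
        fh.write(f"{len(cells)}\n")
        for c, tag in zip(cells, codes):
            fh.write(kind + " " + " ".join(map(str, c)) + f" {tag}\n")
    if isinstance(mesh, VolumetricMesh) and "fiber" in mesh.cell_data:
        with open(base.with_suffix(".lon"), "w") as fh:
            fh.write("1\n")
            np.savetxt(fh, mesh.cell_data["fiber"], fmt="%.9g")
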