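"""Automatic end-diastolic / end-systolic frame selection.

ED defaults to the first frame (the first acquired after R-wave detection in
a typical cine protocol), with the maximum-LV-volume rule as an alternative
policy. ES is the frame minimizing the summed LV-cavity voxel count over the
long-axis views plus the five mid-slices of the short-axis stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import core_io as cio
from .core_io import CineView, SegmentationSeries, StudyBundle


class EDPolicy(str, Enum):
    FIRST_FRAME = "first"
    MAX_LV = "maxlv"


@dataclass
class FramePick:
    ed_frame: int
    es_frame: int
    transients: dict  # view name -> per-frame LV voxel counts
    policy: EDPolicy

    def __post_init__(self):
        if self.ed_frame == self.es_frame:
            raise ValueError("ED and ES frames must differ")


def lv_voxel_transient(series: SegmentationSeries, slices=None) -> np.ndarray:
    """Per-frame LV-cavity voxel counts over the selected slices."""
    if cio.LV_CAVITY not in series.scheme:
        raise ValueError(f"{series.view.value}: no LV_CAVITY in scheme")
    if slices is None:
        slices = range(series.n_slices)
    slices = sorted(set(int(s) for s in slices))
    if not slices:
        raise ValueError("empty slice set")
    if slices[0] < 0 or slices[-1] >= series.n_slices:
        raise IndexError(f"slices {slices} out of range [0,{series.n_slices})")
    lv = series.data[slices] == series.scheme.label(cio.LV_CAVITY)
    return lv.sum(axis=(0, 1, 2)).astype(np.int64)


def mid_slices(n_slices: int) -> list:
    """The five mid-stack slice indices {m-2..m+2}, m = floor(n/2)."""
    if n_slices < 5:
        raise ValueError(
            f"stack has {n_slices} slices; fewer than 5 — pass all slices explicitly"
        )
    m = n_slices // 2
    picked = [m - 2, m - 1, m, m + 1, m + 2]
    return [min(max(s, 0), n_slices - 1) for s in picked]


def _summed_transient(bundle: StudyBundle) -> tuple:
    """Sum of LV transients over LAX views and the SAX mid-slices."""
    transients = {}
    total = None
    for view in (CineView.LAX2CH, CineView.LAX3CH, CineView.LAX4CH, CineView.SAX):
        series = bundle.get(view)
        if series is None or cio.LV_CAVITY not in series.scheme:
            continue
        slices = mid_slices(series.n_slices) if view is CineView.SAX else None
        counts = lv_voxel_transient(series, slices)
        transients[view.value] = counts
        total = counts if total is None else total + counts
    if total is None:
        raise ValueError("no view with an LV cavity label available")
    return transients, total


def pick_es(bundle: StudyBundle) -> int:
    """ES = argmin of the summed LV transient; ties go to the earliest frame."""
    _, total = _summed_transient(bundle)
    return int(np.argmin(total))


def pick_ed(bundle: StudyBundle, policy: EDPolicy = EDPolicy.FIRST_FRAME) -> int:
    if EDPolicy(policy) is EDPolicy.FIRST_FRAME:
        return 0
    _, total = _summed_transient(bundle)
    return int(np.argmax(total))


def pick_frames(bundle: StudyBundle,
                policy: EDPolicy = EDPolicy.FIRST_FRAME) -> FramePick:
    transients, total = _summed_transient(bundle)
    ed = 0 if EDPolicy(policy) is EDPolicy.FIRST_FRAME else int(np.argmax(total))
    es = int(np.argmin(total))
    return FramePick(ed_frame=ed, es_frame=es,
                     transients={k: v.tolist() for k, v in transients.items()},
                     policy=EDPolicy(policy))
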