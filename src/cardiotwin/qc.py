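"""Cohort quality control: the interquartile-range outlier rule.

A participant is excluded from representative-mesh construction when, for at
least one of {LV EDV, RV EDV, LV mass}, the relative difference between the
segmentation-derived and mesh-derived value exceeds the cohort's
Q3 + 1.5 IQR threshold for that phenotype. Thresholds are computed from the
same cohort being judged; exclusion is strict (">"), so a constant cohort
keeps everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

QC_PHENOTYPES = ("lvedv", "rvedv", "lvm")


def relative_difference(seg_value: float, mesh_value: float) -> float:
    """|seg - mesh| / seg with the segmentation value as reference."""
    if seg_value <= 0:
        raise ValueError("reference (segmentation) value must be positive")
    return abs(seg_value - mesh_value) / seg_value


def qc_threshold(values) -> float:
    """Q3 + 1.5 (Q3 - Q1), quantiles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for a quartile threshold")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


@dataclass
class QCResult:
    participant_id: str
    differences: dict  # phenotype -> relative difference
    offending: list = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "EXCLUDED" if self.offending else "KEPT"


def apply_qc(seg_records: dict, mesh_records: dict):
    """Apply the IQR rule over a cohort.

    ``seg_records`` / ``mesh_records`` map participant id to
    :class:`~cardiotwin.phenotypes.PhenotypeRecord` (or any object with
    ``lvedv``/``rvedv``/``lvm``). Unmatched participants are reported and
    excluded from threshold computation. Returns
    ``(results, kept_ids, thresholds, unmatched)``.
    """
    matched = sorted(set(seg_records) & set(mesh_records))
    unmatched = sorted(set(seg_records) ^ set(mesh_records))
    diffs = {
        pid: {ph: relative_difference(getattr(seg_records[pid], ph),
                                      getattr(mesh_records[pid], ph))
              for ph in QC_PHENOTYPES}
        for pid in matched
    }
    thresholds = {ph: qc_threshold([diffs[pid][ph] for pid in matched])
                  for ph in QC_PHENOTYPES}
    results = []
    kept = []
    for pid in matched:
        offending = [ph for ph in QC_PHENOTYPES
                     if diffs[pid][ph] > thresholds[ph]]
        results.append(QCResult(pid, diffs[pid], offending))
        if not offending:
            kept.append(pid)
    return results, kept, thresholds, unmatched
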