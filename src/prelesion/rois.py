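"""Pre-lesion, contralateral and overall-NAWM region geometry.

Filters follow a strict reading of the selection rules: candidate voxels
must be NAWM at every relevant visit and at least 2 mm (exact anisotropic
Euclidean distance; voxels at exactly 2.0 mm are retained) from the
relevant lesion set, and surviving pre-lesion/contralateral pairs must be
exact mirror images of at least 10 voxels each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import LR_AXIS, WM
from .cohort import SubjectSeries
from .lesions import LesionEvent

MIN_ROI_VOXELS = 10
MIN_LESION_DISTANCE_MM = 2.0

ACCEPTED = "accepted"
REJECTED_SIZE = "rejected_size"
REJECTED_TISSUE = "rejected_tissue"
REJECTED_DISTANCE = "rejected_distance"


@dataclass
class ROIPair:
    """Mirror-matched pre-lesion / contralateral NAWM ROI pair."""

    lesion_id: str
    qc_status: str
    prelesion_mask: np.ndarray | None = None
    contralateral_mask: np.ndarray | None = None

    @property
    def accepted(self) -> bool:
        return self.qc_status == ACCEPTED

    @property
    def n_voxels(self) -> int:
        if self.prelesion_mask is None:
            return 0
        return int(self.prelesion_mask.sum())


def reflect_across_midline(mask: np.ndarray) -> np.ndarray:
    """Exact voxel permutation across the inter-columnar midline plane."""
    if mask.shape[LR_AXIS] % 2 != 0:
        raise ValueError(
            "left-right axis extent must be even for exact reflection"
        )
    return np.flip(mask, axis=LR_AXIS).copy()


def _distance_ok(
    lesion_mask: np.ndarray,
    voxel_size_mm,
    min_distance_mm: float = MIN_LESION_DISTANCE_MM,
) -> np.ndarray:
    """Voxels at least ``min_distance_mm`` from any lesion voxel."""
    if not lesion_mask.any():
        return np.ones(lesion_mask.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(
        ~lesion_mask.astype(bool), sampling=voxel_size_mm
    )
    return dist >= min_distance_mm


def compute_overall_nawm(
    series: SubjectSeries, min_distance_mm: float = MIN_LESION_DISTANCE_MM
) -> np.ndarray:
    """NAWM at all visits, >= 2 mm from any-time T2 lesion voxels."""
    nawm = np.ones(series.shape, dtype=bool)
    union = np.zeros(series.shape, dtype=bool)
    for tp in series.timepoints:
        nawm &= tp.labels == WM
        union |= tp.t2_lesion_mask.astype(bool)
    return nawm & _distance_ok(union, series.voxel_size_mm, min_distance_mm)


def define_prelesion_roi(
    event: LesionEvent,
    series: SubjectSeries,
    min_voxels: int = MIN_ROI_VOXELS,
    min_distance_mm: float = MIN_LESION_DISTANCE_MM,
) -> tuple[np.ndarray | None, str]:
    """Seed the pre-lesion ROI from the event's residual new-T2 mask.

    Retains residual voxels that are NAWM at every visit strictly before
    lesion onset and >= 2 mm from every lesion present at those visits
    (any lesion already visible pre-onset counts as pre-existing).
    Returns ``(mask, status)``; rejection is a status, not an error.
    """
    mask = event.residual_mask.astype(bool).copy()
    pre_indices = [
        i for i, w in enumerate(series.weeks) if w < event.first_seen_week
    ]
    for i in pre_indices:
        mask &= series.timepoints[i].labels == WM
    if not mask.any():
        return None, REJECTED_TISSUE
    for i in pre_indices:
        mask &= _distance_ok(
            series.timepoints[i].t2_lesion_mask,
            series.voxel_size_mm,
            min_distance_mm,
        )
    if not mask.any():
        return None, REJECTED_DISTANCE
    if int(mask.sum()) < min_voxels:
        return None, REJECTED_SIZE
    return mask, ACCEPTED


def define_pair(
    prelesion_mask: np.ndarray,
    series: SubjectSeries,
    lesion_id: str = "",
    min_voxels: int = MIN_ROI_VOXELS,
    min_distance_mm: float = MIN_LESION_DISTANCE_MM,
) -> ROIPair:
    """Mirror the pre-lesion ROI and reconcile the pair.

    Contralateral voxels must be NAWM at *all* visits and >= 2 mm from
    any T2 lesion at all visits; adjustments are reflected back so the
    final masks are exact mirrors with at least ``min_voxels`` voxels.
    """
    contra = reflect_across_midline(prelesion_mask.astype(bool))
    nawm_all = np.ones(series.shape, dtype=bool)
    union = np.zeros(series.shape, dtype=bool)
    for tp in series.timepoints:
        nawm_all &= tp.labels == WM
        union |= tp.t2_lesion_mask.astype(bool)
    contra &= nawm_all
    contra &= _distance_ok(union, series.voxel_size_mm, min_distance_mm)
    final_pre = reflect_across_midline(contra)
    if int(contra.sum()) < min_voxels:
        return ROIPair(lesion_id=lesion_id, qc_status=REJECTED_SIZE)
    return ROIPair(
        lesion_id=lesion_id,
        qc_status=ACCEPTED,
        prelesion_mask=final_pre,
        contralateral_mask=contra,
    )


def build_roi_pairs(
    series: SubjectSeries,
    events: list[LesionEvent],
    min_voxels: int = MIN_ROI_VOXELS,
    min_distance_mm: float = MIN_LESION_DISTANCE_MM,
) -> list[ROIPair]:
    """Run the full ROI selection for every tracked event."""
    pairs = []
    for event in events:
        mask, status = define_prelesion_roi(
            event, series, min_voxels=min_voxels, min_distance_mm=min_distance_mm
        )
        if mask is None:
            pairs.append(ROIPair(lesion_id=event.lesion_id, qc_status=status))
            continue
        pair = define_pair(
            mask,
            series,
            lesion_id=event.lesion_id,
            min_voxels=min_voxels,
            min_distance_mm=min_distance_mm,
        )
        pairs.append(pair)
    return pairs


def pair_ledger(pairs_by_subject: dict[str, list[ROIPair]]) -> pd.DataFrame:
    """QC ledger: one row per lesion with status and final pair size."""
    rows = []
    for subject_id, pairs in pairs_by_subject.items():
        for pair in pairs:
            rows.append(
                {
                    "subject_id": subject_id,
                    "lesion_id": pair.lesion_id,
                    "qc_status": pair.qc_status,
                    "n_voxels": pair.n_voxels,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "lesion_id", "qc_status", "n_voxels"]
    )
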