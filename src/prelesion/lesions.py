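"""Detection and longitudinal tracking of new T2 lesions.

New lesions are connected components (26-connectivity) appearing in the
current visit's T2 mask at least one dilation step away from any lesion
present at the previous visit; components touching a dilated previous
lesion are classified as enlargements and excluded.  Events are tracked
to end of study by intersecting with each later T2 mask; whatever remains
at the final visit is the residual new-T2 mask that later seeds the
pre-lesion ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import SubjectSeries

DEFAULT_MIN_VOXELS = 3
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionEvent:
    """A tracked new T2 lesion."""

    lesion_id: str
    subject_id: str
    first_seen_week: int
    prior_reference_week: int
    masks: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def initial_mask(self) -> np.ndarray:
        return self.masks[self.first_seen_week]

    @property
    def residual_mask(self) -> np.ndarray:
        return self.masks[max(self.masks)]

    def residual_volume_mm3(self, voxel_size_mm) -> float:
        return float(self.residual_mask.sum() * np.prod(voxel_size_mm))

    @property
    def onset_interval(self) -> tuple[int, int]:
        """Half-open interval (prior_reference_week, first_seen_week]."""
        return (self.prior_reference_week, self.first_seen_week)


def detect_new_t2(
    prev_mask: np.ndarray,
    curr_mask: np.ndarray,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    dilation_voxels: int = 1,
) -> list[np.ndarray]:
    """Connected new-lesion components between two consecutive visits."""
    if prev_mask.shape != curr_mask.shape:
        raise ValueError("prev and curr masks must share a grid")
    prev_mask = prev_mask.astype(bool)
    curr_mask = curr_mask.astype(bool)
    if prev_mask.any():
        buffer = ndimage.binary_dilation(
            prev_mask, structure=_STRUCT26, iterations=dilation_voxels
        )
    else:
        buffer = prev_mask
    labelled, n = ndimage.label(curr_mask, structure=_STRUCT26)
    components = []
    for i in range(1, n + 1):
        comp = labelled == i
        if (comp & buffer).any():
            continue  # enlargement of an existing lesion, not new
        if comp.sum() >= min_voxels:
            components.append(comp)
    return components


def track_to_end(
    initial_mask: np.ndarray,
    first_seen_week: int,
    prior_reference_week: int,
    subsequent: list[tuple[int, np.ndarray]],
    subject_id: str = "",
    lesion_id: str = "",
) -> LesionEvent:
    """Track one event forward through later T2 lesion masks.

    The tracked mask at each later visit is the overlap of the previous
    tracked mask with that visit's T2 mask, so tracked extent can only
    shrink and the residual is always a subset of the initial component.
    Fully resolved events are retained with residual volume 0.
    """
    event = LesionEvent(
        lesion_id=lesion_id,
        subject_id=subject_id,
        first_seen_week=int(first_seen_week),
        prior_reference_week=int(prior_reference_week),
        masks={int(first_seen_week): initial_mask.astype(bool)},
    )
    tracked = initial_mask.astype(bool)
    for week, mask in subsequent:
        if mask.shape != tracked.shape:
            raise ValueError("tracking masks must share a grid")
        tracked = tracked & mask.astype(bool)
        event.masks[int(week)] = tracked
    return event


def find_lesion_events(
    series: SubjectSeries,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    dilation_voxels: int = 1,
) -> list[LesionEvent]:
    """Detect and track all new T2 lesions across a subject's visits."""
    weeks = series.weeks
    events: list[LesionEvent] = []
    counter = 0
    for i in range(1, len(weeks)):
        prev = series.timepoints[i - 1].t2_lesion_mask
        curr = series.timepoints[i].t2_lesion_mask
        for comp in detect_new_t2(
            prev, curr, min_voxels=min_voxels, dilation_voxels=dilation_voxels
        ):
            later = [
                (weeks[j], series.timepoints[j].t2_lesion_mask)
                for j in range(i + 1, len(weeks))
            ]
            events.append(
                track_to_end(
                    comp,
                    weeks[i],
                    weeks[i - 1],
                    later,
                    subject_id=series.subject_id,
                    lesion_id=f"les-{counter:03d}",
                )
            )
            counter += 1
    return events


def event_table(
    events: list[LesionEvent], voxel_size_mm
) -> pd.DataFrame:
    """Long-format per-event summary (one row per event)."""
    voxvol = float(np.prod(voxel_size_mm))
    rows = [
        {
            "subject_id": ev.subject_id,
            "lesion_id": ev.lesion_id,
            "first_seen_week": ev.first_seen_week,
            "prior_reference_week": ev.prior_reference_week,
            "initial_voxels": int(ev.initial_mask.sum()),
            "residual_voxels": int(ev.residual_mask.sum()),
            "residual_volume_mm3": ev.residual_volume_mm3(voxel_size_mm),
            "initial_volume_mm3": float(ev.initial_mask.sum() * voxvol),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "lesion_id",
            "first_seen_week",
            "prior_reference_week",
            "initial_voxels",
            "residual_voxels",
            "residual_volume_mm3",
            "initial_volume_mm3",
        ],
    )
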