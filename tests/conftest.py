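import numpy as np
import pytest

from prelesion.cohort import (
    PhantomConfig,
    SubjectSeries,
    Timepoint,
    generate_healthy_control,
    generate_ms_subject,
)
from prelesion.constants import CSF, GM, WM


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(noise_sd=0.0, lesion_rate=0.5, seed=1)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config) -> SubjectSeries:
    """One noiseless patient with several lesion events (read-only)."""
    return generate_ms_subject(noiseless_config, "scanner00", seed=7)


@pytest.fixture(scope="session")
def noiseless_control(noiseless_config) -> SubjectSeries:
    return generate_healthy_control(noiseless_config, "scanner00", seed=5)


def make_series(
    t2_masks,
    labels=None,
    weeks=None,
    voxel_size=(1.0, 1.0, 1.0),
    channels=None,
    seed=0,
):
    """Hand-built series for geometry/tracking fixtures.

    ``t2_masks`` is a list of boolean lesion masks (one per visit); the
    label map defaults to WM everywhere inside a one-voxel margin.
    """
    shape = t2_masks[0].shape
    weeks = list(weeks) if weeks is not None else [4 * i for i in range(len(t2_masks))]
    rng = np.random.default_rng(seed)
    timepoints = []
    for i, mask in enumerate(t2_masks):
        if labels is None:
            lab = np.full(shape, WM, dtype=np.uint8)
        else:
            lab = labels[i].copy() if isinstance(labels, list) else labels.copy()
        if channels is None:
            mtr = rng.normal(40.0, 1.0, shape)
            t1w = rng.normal(800.0, 10.0, shape)
            t2w = rng.normal(520.0, 25.0, shape)
        else:
            mtr, t1w, t2w = (c.copy() for c in channels[i])
        timepoints.append(
            Timepoint(
                week=weeks[i],
                mtr=mtr,
                t1w=t1w,
                t2w=t2w,
                labels=lab,
                t2_lesion_mask=mask.astype(bool),
            )
        )
    return SubjectSeries(
        subject_id="fixture",
        scanner_id="scanner00",
        voxel_size_mm=voxel_size,
        timepoints=timepoints,
    )
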