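"""Intensity normalization: scanner-calibrated nMTR, two-stage nT1 and
nT2, and the least-trimmed-squares (LTS) longitudinal affine fit.

Three schemes are implemented:

* nMTR — the median MTR of a reference healthy control's grey matter on a
  given scanner maps to 0 and the white-matter median maps to 1; the same
  affine map is applied to every patient scan from that scanner.
* nT1 — stage 1 maps the baseline grey-matter median to 0 and the
  baseline NAWM median to 1; stage 2 aligns each follow-up to baseline
  with an LTS affine fit before applying the stage-1 map.
* nT2 — stage 1 aligns follow-ups to baseline with LTS; stage 2 z-scores
  against the baseline NAWM mean and standard deviation, so one nT2 unit
  is one baseline NAWM standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .constants import GM, LESION, TISSUE_NAMES, WM
from .cohort import SubjectSeries

DEFAULT_TRIM_FRACTION = 0.5
DEFAULT_N_STARTS = 50
DEFAULT_MAX_ITER = 100
#: Cap on voxels entering an LTS fit; larger masks are subsampled
#: deterministically. ``None`` disables subsampling.
DEFAULT_MAX_VOXELS = 4000


@dataclass(frozen=True)
class ScannerCalibration:
    """Reference healthy-control GM/WM MTR medians for one scanner."""

    scanner_id: str
    median_gm_mtr: float
    median_wm_mtr: float

    def __post_init__(self) -> None:
        if not self.median_wm_mtr > self.median_gm_mtr:
            raise ValueError(
                "calibration requires median WM MTR > median GM MTR "
                f"(got GM={self.median_gm_mtr}, WM={self.median_wm_mtr})"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScannerCalibration":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class AffineIntensityMap:
    """Affine fit ``moving ~ gain * reference + offset`` on the retained
    (trimmed) voxel subset."""

    gain: float
    offset: float
    n_retained: int
    objective: float
    objective_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain) or self.gain == 0:
            raise ValueError("gain must be finite and nonzero")

    def apply(self, reference: np.ndarray) -> np.ndarray:
        return self.gain * reference + self.offset

    def align_to_reference(self, moving: np.ndarray) -> np.ndarray:
        """Map the moving image onto the reference intensity scale."""
        return (moving - self.offset) / self.gain


def calibrate_mtr(
    mtr: np.ndarray, tissue_map: np.ndarray, scanner_id: str = ""
) -> ScannerCalibration:
    """Compute the GM/WM median MTR of a reference healthy control.

    Medians are taken over labelled voxels only; with an even count the
    median is the mean of the two central values (numpy convention).
    """
    medians = {}
    for label in (GM, WM):
        mask = tissue_map == label
        if not mask.any():
            raise ValueError(
                f"empty {TISSUE_NAMES[label]} mask: cannot calibrate MTR"
            )
        medians[label] = float(np.median(mtr[mask]))
    return ScannerCalibration(
        scanner_id=scanner_id,
        median_gm_mtr=medians[GM],
        median_wm_mtr=medians[WM],
    )


def calibrate_mtr_from_series(
    hc_series: SubjectSeries, timepoint: int = 0
) -> ScannerCalibration:
    tp = hc_series.timepoints[timepoint]
    return calibrate_mtr(tp.mtr, tp.labels, scanner_id=hc_series.scanner_id)


def normalize_mtr(
    mtr: np.ndarray, calibration: ScannerCalibration
) -> np.ndarray:
    """Map raw MTR so the calibration GM median -> 0 and WM median -> 1."""
    span = calibration.median_wm_mtr - calibration.median_gm_mtr
    return (mtr - calibration.median_gm_mtr) / span


def denormalize_mtr(
    nmtr: np.ndarray, calibration: ScannerCalibration
) -> np.ndarray:
    """Inverse of :func:`normalize_mtr`."""
    span = calibration.median_wm_mtr - calibration.median_gm_mtr
    return nmtr * span + calibration.median_gm_mtr


# ---------------------------------------------------------------------------
# least-trimmed squares


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate intensities: zero variance on subset")
    gain = float(((x - xm) * (y - ym)).sum()) / sxx
    return gain, ym - gain * xm


def lts_fit(
    reference_volume: np.ndarray,
    moving_volume: np.ndarray,
    mask: np.ndarray,
    fraction: float = DEFAULT_TRIM_FRACTION,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    max_voxels: int | None = DEFAULT_MAX_VOXELS,
) -> AffineIntensityMap:
    """Least-trimmed-squares affine fit ``moving ~ gain*reference + offset``.

    Minimizes the sum of the ``h = floor(fraction * n)`` smallest squared
    residuals via concentration steps (C-steps): fit OLS on the current
    subset, re-select the h voxels with smallest residuals, repeat until
    the subset is a fixed point.  Multiple random starts are used and the
    best objective kept; deterministic under ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if reference_volume.shape != moving_volume.shape:
        raise ValueError("reference and moving volumes must share a grid")
    x = np.asarray(reference_volume, dtype=float)[mask]
    y = np.asarray(moving_volume, dtype=float)[mask]
    rng = np.random.default_rng(seed)
    if max_voxels is not None and x.size > max_voxels:
        keep = rng.choice(x.size, size=max_voxels, replace=False)
        x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"mask too small for an LTS fit (n={n})")
    h = int(np.floor(fraction * n))
    if h < 2:
        raise ValueError("trimmed subset must keep at least 2 voxels")

    if h == n:  # no trimming: plain OLS
        gain, offset = _ols(x, y)
        resid = y - (gain * x + offset)
        obj = float((resid**2).sum())
        return AffineIntensityMap(gain, offset, n, obj, (obj,))

    def c_steps(subset: np.ndarray):
        history = []
        for _ in range(max_iter):
            gain, offset = _ols(x[subset], y[subset])
            resid2 = (y - (gain * x + offset)) ** 2
            history.append(float(resid2[subset].sum()))
            new = np.sort(np.argpartition(resid2, h - 1)[:h])
            if new.size == subset.size and np.array_equal(new, subset):
                break
            subset = new
        obj = float(resid2[subset].sum())
        history.append(obj)
        return gain, offset, subset, obj, history

    best = None
    # deterministic start from the full-data OLS, then random h-subsets
    gain0, offset0 = _ols(x, y)
    r2_full = (y - (gain0 * x + offset0)) ** 2
    starts = [np.sort(np.argpartition(r2_full, h - 1)[:h])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.sort(rng.choice(n, size=h, replace=False)))

    for subset in starts:
        try:
            result = c_steps(subset)
        except ValueError:
            continue  # degenerate subset; try another start
        if best is None or result[3] < best[3]:
            best = result
    if best is None:
        raise ValueError("degenerate intensities: all LTS starts failed")
    gain, offset, subset, obj, history = best
    if gain == 0.0:
        raise ValueError("degenerate fit: zero gain")
    return AffineIntensityMap(
        gain=float(gain),
        offset=float(offset),
        n_retained=int(h),
        objective=obj,
        objective_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# two-stage longitudinal schemes


def _lts_mask(series: SubjectSeries, index: int, scope: str) -> np.ndarray:
    """Voxels entering the longitudinal LTS fit for timepoint ``index``.

    Default scope is whole brain excluding voxels lesional at either the
    baseline or the follow-up visit.
    """
    base = series.baseline
    curr = series.timepoints[index]
    if scope == "brain":
        mask = base.labels > 0
        mask &= ~(base.t2_lesion_mask | curr.t2_lesion_mask)
    elif scope == "nawm":
        mask = (base.labels == WM) & (curr.labels == WM)
    else:
        raise ValueError(f"unknown LTS scope {scope!r}")
    return mask


def _align_series(
    series: SubjectSeries,
    channel: str,
    fraction: float,
    seed: int,
    lts_scope: str,
) -> list[np.ndarray]:
    """LTS-align every follow-up of ``channel`` to the baseline scan."""
    base = series.baseline.channel(channel)
    aligned = [np.asarray(base, dtype=float)]
    for i, tp in enumerate(series.timepoints[1:], start=1):
        fit = lts_fit(
            base,
            tp.channel(channel),
            _lts_mask(series, i, lts_scope),
            fraction=fraction,
            seed=seed + i,
        )
        aligned.append(fit.align_to_reference(np.asarray(tp.channel(channel), dtype=float)))
    return aligned


def normalize_t1(
    series: SubjectSeries,
    fraction: float = DEFAULT_TRIM_FRACTION,
    seed: int = 0,
    lts_scope: str = "brain",
) -> list[np.ndarray]:
    """Two-stage T1w normalization.

    Returns one nT1 volume per timepoint; the baseline output has
    median(GM) = 0 and median(NAWM) = 1 exactly.
    """
    labels = series.baseline.labels
    gm_mask = labels == GM
    nawm_mask = labels == WM
    if not gm_mask.any():
        raise ValueError("empty gm mask in baseline tissue map")
    if not nawm_mask.any():
        raise ValueError("empty nawm mask in baseline tissue map")
    base_t1 = np.asarray(series.baseline.t1w, dtype=float)
    gm_med = float(np.median(base_t1[gm_mask]))
    nawm_med = float(np.median(base_t1[nawm_mask]))
    if nawm_med == gm_med:
        raise ValueError("degenerate T1 baseline: GM and NAWM medians equal")
    aligned = _align_series(series, "t1w", fraction, seed, lts_scope)
    return [(v - gm_med) / (nawm_med - gm_med) for v in aligned]


def normalize_t2(
    series: SubjectSeries,
    fraction: float = DEFAULT_TRIM_FRACTION,
    seed: int = 0,
    lts_scope: str = "brain",
) -> list[np.ndarray]:
    """Two-stage T2w normalization.

    Stage 1 LTS-aligns follow-ups to baseline; stage 2 z-scores against
    the baseline NAWM mean/SD, so the baseline output has mean(NAWM) = 0
    and SD(NAWM) = 1 exactly and one unit equals one baseline NAWM SD.
    """
    nawm_mask = series.baseline.labels == WM
    if not nawm_mask.any():
        raise ValueError("empty nawm mask in baseline tissue map")
    base_t2 = np.asarray(series.baseline.t2w, dtype=float)
    mean = float(base_t2[nawm_mask].mean())
    sd = float(base_t2[nawm_mask].std())
    if sd == 0.0:
        raise ValueError("zero NAWM intensity SD: cannot scale nT2")
    aligned = _align_series(series, "t2w", fraction, seed, lts_scope)
    return [(v - mean) / sd for v in aligned]
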