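"""Voxel-wise atlases: mean nMTR in NAWM, HC - PwMS difference, the T2
lesion probability atlas, probability bins, the linear-trend likelihood
ratio test, and ROI-by-bin frequency distributions.

All volumes are assumed to live on one shared template grid (synthetic
cohorts are generated in a single space; registration is identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: Default lowest bin edge: voxels with lesion probability below this are
#: pooled into the minimal-probability bin.
FIRST_BIN_EDGE = 0.0025


@dataclass
class MeanIntensityAtlas:
    """Per-voxel mean normalized intensity with subject coverage."""

    mean: np.ndarray  # NaN where coverage is 0
    coverage: np.ndarray  # contributing subjects per voxel
    n_subjects: int
    cohort: str = ""


@dataclass
class ProbabilityAtlas:
    p: np.ndarray
    n_subjects: int
    bin_edges: np.ndarray | None = None
    bin_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def build_mean_atlas(
    volumes: list[np.ndarray],
    masks: list[np.ndarray],
    cohort: str = "",
) -> MeanIntensityAtlas:
    """Average each voxel over the subjects whose mask includes it."""
    if len(volumes) != len(masks):
        raise ValueError("need one mask per volume")
    shape = volumes[0].shape
    total = np.zeros(shape)
    coverage = np.zeros(shape, dtype=int)
    for vol, mask in zip(volumes, masks):
        if vol.shape != shape or mask.shape != shape:
            raise ValueError("all volumes and masks must share a grid")
        m = mask.astype(bool)
        total[m] += vol[m]
        coverage += m
    with np.errstate(invalid="ignore"):
        mean = np.where(coverage > 0, total / np.maximum(coverage, 1), np.nan)
    return MeanIntensityAtlas(
        mean=mean, coverage=coverage, n_subjects=len(volumes), cohort=cohort
    )


def difference_atlas(
    hc_atlas: MeanIntensityAtlas,
    pwms_atlas: MeanIntensityAtlas,
    min_coverage: int | None = None,
) -> np.ndarray:
    """Voxel-wise HC - PwMS mean difference; NaN below min coverage.

    ``min_coverage`` defaults to 25% of each cohort's subject count.
    """
    if hc_atlas.mean.shape != pwms_atlas.mean.shape:
        raise ValueError("atlases must share a grid")
    cov_hc = (
        min_coverage
        if min_coverage is not None
        else int(np.ceil(0.25 * hc_atlas.n_subjects))
    )
    cov_ms = (
        min_coverage
        if min_coverage is not None
        else int(np.ceil(0.25 * pwms_atlas.n_subjects))
    )
    ok = (hc_atlas.coverage >= max(cov_hc, 1)) & (
        pwms_atlas.coverage >= max(cov_ms, 1)
    )
    diff = np.full(hc_atlas.mean.shape, np.nan)
    diff[ok] = hc_atlas.mean[ok] - pwms_atlas.mean[ok]
    return diff


def build_probability_atlas(
    lesion_masks: list[np.ndarray], n_subjects: int | None = None
) -> ProbabilityAtlas:
    """Sum binary per-subject lesion masks and divide by subject count."""
    n = n_subjects if n_subjects is not None else len(lesion_masks)
    total = np.zeros(lesion_masks[0].shape)
    for mask in lesion_masks:
        arr = np.asarray(mask)
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("lesion masks must be binary")
        total += arr
    return ProbabilityAtlas(p=total / n, n_subjects=n)


def discretize_probability(
    atlas: ProbabilityAtlas,
    n_bins: int = 4,
    edges: np.ndarray | None = None,
    mode: str = "log",
    mask: np.ndarray | None = None,
    first_edge: float = FIRST_BIN_EDGE,
) -> ProbabilityAtlas:
    """Assign a categorical probability bin (1..n_bins) to each voxel.

    Bins are right-open over increasing probability; bin 1 is anchored at
    ``p < first_edge``.  ``mode='log'`` spaces the remaining edges evenly
    in log probability; ``mode='equal_count'`` splits the masked voxels
    into rank-based bins whose counts differ by at most one.  Voxels
    outside ``mask`` get label 0.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    p = atlas.p
    m = np.ones(p.shape, dtype=bool) if mask is None else mask.astype(bool)
    labels = np.zeros(p.shape, dtype=int)

    if mode == "equal_count" and edges is None:
        vals = p[m]
        order = np.argsort(vals, kind="stable")
        chunk_labels = np.empty(vals.size, dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
            chunk_labels[chunk] = b
        labels[m] = chunk_labels
        edges_out = np.array(
            [vals.min()]
            + [
                np.max(vals[chunk_labels == b]) if (chunk_labels == b).any() else np.nan
                for b in range(1, n_bins + 1)
            ]
        )
        return ProbabilityAtlas(
            p=p,
            n_subjects=atlas.n_subjects,
            bin_edges=edges_out,
            bin_labels=labels,
        )

    if edges is None:
        pmax = float(p[m].max())
        if pmax <= first_edge:
            raise ValueError(
                "maximum probability does not exceed the first bin edge"
            )
        inner = np.logspace(
            np.log10(first_edge), np.log10(pmax), n_bins
        )
        edges = np.concatenate([[0.0], inner[:-1], [np.inf]])
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    # right-open bins: label b covers edges[b-1] <= p < edges[b]
    labels_m = np.digitize(p[m], edges[1:-1], right=False) + 1
    labels[m] = labels_m
    return ProbabilityAtlas(
        p=p, n_subjects=atlas.n_subjects, bin_edges=edges, bin_labels=labels
    )


def trend_test(
    values: np.ndarray,
    bins: np.ndarray,
    populations: np.ndarray,
) -> dict:
    """Likelihood-ratio test for a linear bin x population interaction.

    ``values`` are per-subject (one row per subject x bin) mean nMTR;
    the full model regresses value on bin (continuous linear term),
    population, and their interaction; the null drops the interaction.
    Statistic = 2 * delta-loglik (ML), p from chi-square with df equal to
    the parameter difference.
    """
    values = np.asarray(values, dtype=float)
    bins = np.asarray(bins, dtype=float)
    populations = np.asarray(populations)
    pops = np.unique(populations)
    if len(pops) != 2:
        raise ValueError("exactly two populations are required")
    if len(np.unique(bins)) < 2:
        raise ValueError("need at least 2 bins")
    empty = [
        (b, pop)
        for b in np.unique(bins)
        for pop in pops
        if not np.any((bins == b) & (populations == pop))
    ]
    if empty:
        raise ValueError(f"empty bin x population cells: {empty}")

    pop_ind = (populations == pops[1]).astype(float)
    X_null = sm.add_constant(
        np.column_stack([bins, pop_ind]), has_constant="add"
    )
    X_full = sm.add_constant(
        np.column_stack([bins, pop_ind, bins * pop_ind]), has_constant="add"
    )
    ll_null = sm.OLS(values, X_null).fit().llf
    ll_full = sm.OLS(values, X_full).fit().llf
    stat = 2.0 * (ll_full - ll_null)
    df = X_full.shape[1] - X_null.shape[1]
    return {
        "statistic": float(stat),
        "df": int(df),
        "p": float(sps.chi2.sf(max(stat, 0.0), df)),
    }


def roi_bin_distribution(
    roi_masks: dict[str, np.ndarray], binned: ProbabilityAtlas
) -> pd.DataFrame:
    """Fraction of each ROI class's voxels falling in each bin."""
    if binned.bin_labels is None:
        raise ValueError("atlas has no bin labels; run discretize_probability")
    labels = binned.bin_labels
    bins = sorted(b for b in np.unique(labels) if b > 0)
    rows = []
    for name, mask in roi_masks.items():
        m = mask.astype(bool)
        n = int(m.sum())
        for b in bins:
            count = int((labels[m] == b).sum())
            rows.append(
                {
                    "roi_class": name,
                    "bin": int(b),
                    "count": count,
                    "fraction": count / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["roi_class", "bin", "count", "fraction"])
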