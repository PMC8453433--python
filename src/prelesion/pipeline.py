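"""End-to-end orchestration: simulate -> normalize -> track -> rois ->
stats -> atlas, with reproducible configuration and TSV/JSON reports.

Stages communicate through plain data structures in memory and persist
their outputs as NIfTI/TSV/JSON; every table carries the configuration
hash so reruns with an identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import io as io_mod
from . import lesions as lesions_mod
from . import normalize as norm_mod
from . import rois as rois_mod
from . import stats as stats_mod
from .cohort import Cohort, PhantomConfig, SubjectSeries, generate_cohort
from .constants import WM

log = logging.getLogger(__name__)

TRIAL_MODES = {
    # analysed visit schedules; SYNERGY-style monthly scans exclude the
    # final pre-onset interval visit from the longitudinal analysis
    "synergy_monthly": {
        "visit_weeks": (0, 4, 8, 12, 16, 20, 24),
        "exclude_final_interval": True,
    },
    "ascend_semiannual": {
        "visit_weeks": (0, 24, 48, 72, 96),
        "exclude_final_interval": False,
    },
    "advance_annual": {
        "visit_weeks": (0, 48, 96, 144),
        "exclude_final_interval": False,
    },
}


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    trial_mode: str = "synergy_monthly"
    covariates: tuple[str, ...] = ("age", "sex", "treatment_group")
    channels: tuple[str, ...] = ("nmtr", "nt1", "nt2")
    contrasts: tuple[str, ...] = stats_mod.CONTRASTS
    min_roi_voxels: int = rois_mod.MIN_ROI_VOXELS
    min_lesion_distance_mm: float = rois_mod.MIN_LESION_DISTANCE_MM
    detection_min_voxels: int = lesions_mod.DEFAULT_MIN_VOXELS
    lts_fraction: float = norm_mod.DEFAULT_TRIM_FRACTION
    multiplicity: str = "holm"
    n_probability_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_mode not in TRIAL_MODES:
            raise ValueError(
                f"trial_mode must be one of {sorted(TRIAL_MODES)}"
            )
        mode = TRIAL_MODES[self.trial_mode]
        if tuple(self.phantom.visit_weeks) != mode["visit_weeks"]:
            self.phantom = dataclasses.replace(
                self.phantom, visit_weeks=mode["visit_weeks"]
            )

    @property
    def exclude_final_interval(self) -> bool:
        return TRIAL_MODES[self.trial_mode]["exclude_final_interval"]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom_raw = raw.pop("phantom", {})
        for key in (
            "grid_shape",
            "voxel_size_mm",
            "visit_weeks",
            "lesion_radius_mm",
        ):
            if key in phantom_raw and phantom_raw[key] is not None:
                phantom_raw[key] = tuple(phantom_raw[key])
        for key in ("covariates", "channels", "contrasts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(phantom=PhantomConfig(**phantom_raw), **raw)


def analyse_subject(
    series: SubjectSeries,
    calibration: norm_mod.ScannerCalibration,
    config: RunConfig,
) -> stats_mod.SubjectAnalysis:
    """Normalize one subject's channels, track lesions and build ROIs."""
    normalized = {}
    if "nmtr" in config.channels:
        normalized["nmtr"] = [
            norm_mod.normalize_mtr(tp.mtr, calibration)
            for tp in series.timepoints
        ]
    if "nt1" in config.channels:
        normalized["nt1"] = norm_mod.normalize_t1(
            series, fraction=config.lts_fraction, seed=config.seed
        )
    if "nt2" in config.channels:
        normalized["nt2"] = norm_mod.normalize_t2(
            series, fraction=config.lts_fraction, seed=config.seed
        )
    events = lesions_mod.find_lesion_events(
        series, min_voxels=config.detection_min_voxels
    )
    pairs = rois_mod.build_roi_pairs(
        series,
        events,
        min_voxels=config.min_roi_voxels,
        min_distance_mm=config.min_lesion_distance_mm,
    )
    overall = rois_mod.compute_overall_nawm(
        series, min_distance_mm=config.min_lesion_distance_mm
    )
    return stats_mod.SubjectAnalysis(
        subject_id=series.subject_id,
        weeks=series.weeks,
        events=events,
        pairs=pairs,
        overall_nawm=overall,
        normalized=normalized,
        covariates=series.covariates,
        voxel_volume_mm3=float(np.prod(series.voxel_size_mm)),
    )


@dataclass
class PipelineResult:
    cohort: Cohort
    analyses: list[stats_mod.SubjectAnalysis]
    sample_table: pd.DataFrame
    ls_means: pd.DataFrame
    model_summaries: pd.DataFrame
    roi_ledger: pd.DataFrame
    atlas_report: dict
    bin_distribution: pd.DataFrame


def _fit_all_models(
    table: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LS-means by time for every contrast x channel combination."""
    ls_rows = []
    model_rows = []
    for channel in config.channels:
        for contrast in config.contrasts:
            sub = table[
                (table["channel"] == channel)
                & (table["contrast"] == contrast)
            ]
            if sub.empty or sub["weeks_before_onset"].nunique() < 2:
                log.warning(
                    "skipping %s/%s: insufficient data", channel, contrast
                )
                continue
            try:
                fit = stats_mod.fit_weighted_lmm(
                    sub, covariates=config.covariates
                )
            except (ValueError, RuntimeError) as exc:
                log.warning("fit failed for %s/%s: %s", channel, contrast, exc)
                continue
            lsm = stats_mod.ls_means(fit, adjust=config.multiplicity)
            lsm.insert(0, "contrast", contrast)
            lsm.insert(0, "channel", channel)
            ls_rows.append(lsm)
            model_rows.append(
                {
                    "channel": channel,
                    "contrast": contrast,
                    "sigma_p2": fit.sigma_p2,
                    "sigma_l2": fit.sigma_l2,
                    "sigma2": fit.sigma2,
                    "rho": fit.rho,
                    "loglik": fit.loglik,
                    "nobs": fit.nobs,
                    "converged": fit.converged,
                }
            )
    ls_df = (
        pd.concat(ls_rows, ignore_index=True) if ls_rows else pd.DataFrame()
    )
    return ls_df, pd.DataFrame(model_rows)


def _atlas_stage(
    cohort: Cohort,
    analyses: list[stats_mod.SubjectAnalysis],
    calibrations: dict[str, norm_mod.ScannerCalibration],
    config: RunConfig,
) -> tuple[dict, pd.DataFrame]:
    """nMTR atlases, difference, lesion-probability bins and trend test."""
    controls = cohort.all_controls
    hc_vols, hc_masks = [], []
    for hc in controls:
        cal = calibrations[hc.scanner_id]
        hc_vols.append(norm_mod.normalize_mtr(hc.baseline.mtr, cal))
        hc_masks.append(hc.baseline.labels == WM)
    ms_vols, ms_masks, lesion_masks = [], [], []
    for series, an in zip(cohort.subjects, analyses):
        cal = calibrations[series.scanner_id]
        ms_vols.append(norm_mod.normalize_mtr(series.baseline.mtr, cal))
        ms_masks.append(series.baseline.labels == WM)
        union = np.zeros(series.shape, dtype=bool)
        for tp in series.timepoints:
            union |= tp.t2_lesion_mask.astype(bool)
        lesion_masks.append(union)

    hc_atlas = atlas_mod.build_mean_atlas(hc_vols, hc_masks, cohort="HC")
    ms_atlas = atlas_mod.build_mean_atlas(ms_vols, ms_masks, cohort="PwMS")
    diff = atlas_mod.difference_atlas(hc_atlas, ms_atlas)
    prob = atlas_mod.build_probability_atlas(
        [m.astype(np.uint8) for m in lesion_masks]
    )
    wm_mask = cohort.subjects[0].baseline.labels == WM
    binned = atlas_mod.discretize_probability(
        prob, n_bins=config.n_probability_bins, mask=wm_mask
    )

    # per-subject mean nMTR per bin, both populations, for the trend test
    trend_rows = []
    for pop, vols, masks in (
        ("HC", hc_vols, hc_masks),
        ("PwMS", ms_vols, ms_masks),
    ):
        for i, (vol, mask) in enumerate(zip(vols, masks)):
            for b in range(1, config.n_probability_bins + 1):
                sel = mask & (binned.bin_labels == b)
                if sel.any():
                    trend_rows.append(
                        {
                            "population": pop,
                            "subject_index": i,
                            "bin": b,
                            "mean_nmtr": float(vol[sel].mean()),
                        }
                    )
    trend_df = pd.DataFrame(trend_rows)
    try:
        trend = atlas_mod.trend_test(
            trend_df["mean_nmtr"].to_numpy(),
            trend_df["bin"].to_numpy(),
            trend_df["population"].to_numpy(),
        )
    except ValueError as exc:
        log.warning("trend test unavailable: %s", exc)
        trend = {"statistic": np.nan, "df": 0, "p": np.nan}

    # ROI-class frequency distribution over bins (Fig 7B analogue)
    shape = cohort.subjects[0].shape
    class_masks = {
        "prelesion": np.zeros(shape, dtype=bool),
        "contralateral": np.zeros(shape, dtype=bool),
        "overall": np.zeros(shape, dtype=bool),
    }
    for an in analyses:
        class_masks["overall"] |= an.overall_nawm
        for pair in an.pairs:
            if pair.accepted:
                class_masks["prelesion"] |= pair.prelesion_mask
                class_masks["contralateral"] |= pair.contralateral_mask
    bin_dist = atlas_mod.roi_bin_distribution(class_masks, binned)

    per_bin_diff = []
    for b in range(1, config.n_probability_bins + 1):
        sel = (binned.bin_labels == b) & ~np.isnan(diff)
        per_bin_diff.append(
            float(np.nanmean(diff[sel])) if sel.any() else np.nan
        )
    report = {
        "trend_test": trend,
        "bin_edges": [float(e) for e in np.ravel(binned.bin_edges)],
        "mean_difference_by_bin": per_bin_diff,
        "n_hc": len(hc_vols),
        "n_pwms": len(ms_vols),
    }
    return report, bin_dist


def run_pipeline(
    config: RunConfig, outdir: Path | None = None
) -> PipelineResult:
    """Execute all stages and (optionally) persist the report bundle."""
    chash = io_mod.config_hash(config.to_dict())
    log.info("pipeline start (config %s)", chash)

    cohort = generate_cohort(config.phantom)
    calibrations = {
        sid: norm_mod.calibrate_mtr_from_series(hc)
        for sid, hc in cohort.controls.items()
    }
    analyses = [
        analyse_subject(series, calibrations[series.scanner_id], config)
        for series in cohort.subjects
    ]
    table = stats_mod.build_sample_table(
        analyses, exclude_final_interval=config.exclude_final_interval
    )
    ls_df, model_df = _fit_all_models(table, config)
    ledger = rois_mod.pair_ledger(
        {an.subject_id: an.pairs for an in analyses}
    )
    atlas_report, bin_dist = _atlas_stage(
        cohort, analyses, calibrations, config
    )

    result = PipelineResult(
        cohort=cohort,
        analyses=analyses,
        sample_table=table,
        ls_means=ls_df,
        model_summaries=model_df,
        roi_ledger=ledger,
        atlas_report=atlas_report,
        bin_distribution=bin_dist,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_mod.write_table(table, outdir / "sample_table.tsv", chash)
        io_mod.write_table(ls_df, outdir / "ls_means.tsv", chash)
        io_mod.write_table(model_df, outdir / "model_summaries.tsv", chash)
        io_mod.write_table(ledger, outdir / "roi_ledger.tsv", chash)
        io_mod.write_table(bin_dist, outdir / "roi_bin_distribution.tsv", chash)
        io_mod.write_table(cohort.truth, outdir / "truth.tsv", chash)
        qc = ledger.groupby("qc_status").size().rename("count").reset_index()
        io_mod.write_table(qc, outdir / "roi_qc_counts.tsv", chash)
        with open(outdir / "atlas_report.json", "w") as fh:
            json.dump(
                {"config_hash": chash, **atlas_report}, fh, indent=2,
                sort_keys=True,
            )
        for sid, cal in calibrations.items():
            (outdir / f"calibration_{sid}.json").write_text(cal.to_json())
    log.info(
        "pipeline done: %d subjects, %d sample rows",
        len(cohort.subjects),
        len(table),
    )
    return result
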