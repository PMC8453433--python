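"""NIfTI / TSV / YAML / JSON round-tripping for cohorts and artifacts."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, PhantomConfig, SubjectSeries, Timepoint
from .constants import CHANNELS


def affine_from_voxel_size(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(volume: np.ndarray, voxel_size_mm, path: Path) -> None:
    if volume.dtype == bool:
        volume = volume.astype(np.uint8)
    img = nib.Nifti1Image(volume, affine_from_voxel_size(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def config_hash(config: PhantomConfig | dict) -> str:
    """Stable short hash identifying a run configuration."""
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    text = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, cfg_hash: str = "") -> None:
    """TSV with a leading config-hash comment line."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_to_yaml(config: PhantomConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def config_from_yaml(path: Path) -> PhantomConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("grid_shape", "voxel_size_mm", "visit_weeks", "lesion_radius_mm"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PhantomConfig(**raw)


def _series_dir(root: Path, subject_id: str) -> Path:
    return root / subject_id


def write_series(series: SubjectSeries, root: Path) -> None:
    out = _series_dir(root, series.subject_id)
    out.mkdir(parents=True, exist_ok=True)
    for tp in series.timepoints:
        stem = f"sub-{series.subject_id}_wk-{tp.week:03d}"
        for ch in CHANNELS:
            save_volume(
                tp.channel(ch), series.voxel_size_mm, out / f"{stem}_{ch}.nii.gz"
            )
        save_volume(tp.labels, series.voxel_size_mm, out / f"{stem}_labels.nii.gz")
        save_volume(
            tp.t2_lesion_mask, series.voxel_size_mm, out / f"{stem}_t2mask.nii.gz"
        )


def read_series(
    root: Path, subject_id: str, scanner_id: str, weeks, covariates=None
) -> SubjectSeries:
    src = _series_dir(root, subject_id)
    timepoints = []
    voxel_size = None
    for week in weeks:
        stem = f"sub-{subject_id}_wk-{int(week):03d}"
        channels = {}
        for ch in CHANNELS:
            vol, voxel_size = load_volume(src / f"{stem}_{ch}.nii.gz")
            channels[ch] = np.asarray(vol, dtype=float)
        labels, _ = load_volume(src / f"{stem}_labels.nii.gz")
        mask, _ = load_volume(src / f"{stem}_t2mask.nii.gz")
        timepoints.append(
            Timepoint(
                week=int(week),
                mtr=channels["mtr"],
                t1w=channels["t1w"],
                t2w=channels["t2w"],
                labels=np.asarray(labels, dtype=np.uint8),
                t2_lesion_mask=np.asarray(mask, dtype=bool),
            )
        )
    return SubjectSeries(
        subject_id=subject_id,
        scanner_id=scanner_id,
        voxel_size_mm=voxel_size,
        timepoints=timepoints,
        covariates=covariates or {},
    )


def write_cohort(cohort: Cohort, root: Path, overwrite: bool = False) -> None:
    """Write a cohort directory: NIfTI volumes, covariate and truth TSVs
    and the config YAML.  Refuses to clobber existing output unless
    ``overwrite`` is set."""
    root = Path(root)
    marker = root / "cohort.yaml"
    if marker.exists() and not overwrite:
        raise FileExistsError(
            f"{marker} exists; pass overwrite=True to replace the cohort"
        )
    root.mkdir(parents=True, exist_ok=True)
    config_to_yaml(cohort.config, marker)
    chash = config_hash(cohort.config)
    write_table(cohort.covariates, root / "covariates.tsv", chash)
    write_table(cohort.truth, root / "truth.tsv", chash)
    scanner_rows = []
    for series in cohort.subjects:
        write_series(series, root / "subjects")
    for scanner_id, series in cohort.controls.items():
        write_series(series, root / "controls")
        scanner_rows.append(
            {"scanner_id": scanner_id, "control_id": series.subject_id}
        )
    for series in cohort.extra_controls:
        write_series(series, root / "controls")
        scanner_rows.append(
            {"scanner_id": series.scanner_id, "control_id": series.subject_id}
        )
    write_table(
        pd.DataFrame(scanner_rows, columns=["scanner_id", "control_id"]),
        root / "controls.tsv",
        chash,
    )


def read_cohort(root: Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Ground-truth event masks are not rehydrated (the ledger TSV carries
    the summary); downstream stages re-detect events from the masks.
    """
    root = Path(root)
    config = config_from_yaml(root / "cohort.yaml")
    covariates = read_table(root / "covariates.tsv")
    truth = read_table(root / "truth.tsv")
    controls_tbl = read_table(root / "controls.tsv")
    subjects = []
    for _, row in covariates.iterrows():
        cov = row.drop(["subject_id", "scanner_id"]).to_dict()
        subjects.append(
            read_series(
                root / "subjects",
                row["subject_id"],
                row["scanner_id"],
                config.visit_weeks,
                covariates=cov,
            )
        )
    controls: dict[str, SubjectSeries] = {}
    extra: list[SubjectSeries] = []
    for _, row in controls_tbl.iterrows():
        series = read_series(
            root / "controls",
            row["control_id"],
            row["scanner_id"],
            config.visit_weeks,
        )
        if row["scanner_id"] not in controls:
            controls[row["scanner_id"]] = series
        else:
            extra.append(series)
    return Cohort(
        config=config,
        subjects=subjects,
        controls=controls,
        covariates=covariates,
        truth=truth,
        extra_controls=extra,
    )
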