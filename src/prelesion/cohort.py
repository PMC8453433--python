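"""Synthetic longitudinal multi-channel brain cohorts.

Generates left-right symmetric brain phantoms (GM / WM / CSF ventricles)
with scheduled new-lesion events, scanner-specific affine intensity
distortion, per-visit acquisition drift, and configurable pre-lesion
signal abnormalities injected on the *normalized* intensity scales so the
downstream normalization pipeline can recover them exactly on noiseless
data.  Every generated series carries its own ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .constants import BACKGROUND, CHANNELS, CSF, GM, LESION, LR_AXIS, WM

log = logging.getLogger(__name__)

# Raw (arbitrary-unit) tissue intensity anchors per channel.  MTR and T1w
# are expressed through normalized-scale tissue fields anchored at the GM
# and WM medians; T2w is anchored at the NAWM mean with T2_NAWM_SD as the
# unit of within-NAWM spread.
MTR_GM = 30.0
MTR_WM = 42.0
MTR_FIELD = {CSF: -2.0, GM: 0.0, WM: 1.0, LESION: 0.35}
T1_GM = 400.0
T1_WM = 800.0
T1_FIELD = {CSF: -0.6, GM: 0.0, WM: 1.0, LESION: 0.35}
T2_NAWM_MEAN = 520.0
T2_NAWM_SD = 25.0
T2_BASE = {CSF: 1100.0, GM: 650.0, WM: T2_NAWM_MEAN}
T2_LESION = T2_NAWM_MEAN + 6.0 * T2_NAWM_SD

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic cohort.

    ``prelesion_delta_nmtr`` is a *decrement* on the nMTR scale (healthy
    GM -> 0, healthy WM -> 1); ``prelesion_delta_nt2`` is an *increment*
    in baseline-NAWM standard-deviation units.  ``noise_sd`` is additive
    Gaussian noise expressed in units of each channel's normalized scale.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_subjects: int = 8
    visit_weeks: tuple[int, ...] = (0, 4, 8, 12, 16, 20, 24)
    n_scanners: int = 1
    n_controls: int | None = None
    scanner_profiles: dict | None = None
    lesion_rate: float = 0.25
    prelesion_delta_nmtr: float = 0.2
    prelesion_delta_nt2: float = 0.3
    contralateral_fraction: float = 0.0
    noise_sd: float = 0.0
    mtr_gradient_amplitude: float = 0.05
    mtr_gradient_scale_mm: float = 12.0
    #: diffuse patient-only NAWM nMTR decrement proportional to the
    #: lesion-probability field (periventricular-peaked); zero keeps
    #: patient NAWM identical to controls outside injected footprints
    nawm_decrement_amplitude: float = 0.0
    lesion_field_scale_mm: float = 10.0
    lesion_radius_mm: tuple[float, float] = (2.0, 6.0)
    drift_gain_sd: float = 0.05
    drift_offset_sd: float = 0.02
    onset_ramp: bool = False
    onset_ramp_weeks: float = 24.0
    max_placement_attempts: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or len(self.voxel_size_mm) != 3:
            raise ValueError("grid_shape and voxel_size_mm must be 3-tuples")
        if self.grid_shape[LR_AXIS] % 2 != 0:
            raise ValueError(
                "grid_shape must be even along the left-right axis so the "
                "midline falls between two voxel columns"
            )
        weeks = np.asarray(self.visit_weeks)
        if len(weeks) < 1 or np.any(np.diff(weeks) <= 0):
            raise ValueError("visit_weeks must be strictly increasing")
        if not 0.0 <= self.contralateral_fraction <= 1.0:
            raise ValueError("contralateral_fraction must lie in [0, 1]")
        if self.lesion_rate < 0:
            raise ValueError("lesion_rate must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return len(self.visit_weeks)

    @property
    def scanner_ids(self) -> tuple[str, ...]:
        if self.scanner_profiles is not None:
            return tuple(self.scanner_profiles)
        return tuple(f"scanner{i:02d}" for i in range(self.n_scanners))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class TruthEvent:
    """Ground truth for one injected lesion event."""

    lesion_id: str
    onset_week: int
    footprint: np.ndarray
    mirror: np.ndarray
    delta_nmtr: float
    delta_nt2: float
    contralateral_fraction: float

    @property
    def n_voxels(self) -> int:
        return int(self.footprint.sum())


@dataclass
class Timepoint:
    week: int
    mtr: np.ndarray
    t1w: np.ndarray
    t2w: np.ndarray
    labels: np.ndarray
    t2_lesion_mask: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class SubjectSeries:
    """One subject's ordered, co-registered longitudinal timepoints."""

    subject_id: str
    scanner_id: str
    voxel_size_mm: tuple[float, float, float]
    timepoints: list[Timepoint]
    covariates: dict = field(default_factory=dict)
    truth: list[TruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {tp.labels.shape for tp in self.timepoints}
        if len(shapes) > 1:
            raise ValueError("all timepoints must share one grid")
        for tp in self.timepoints:
            if np.any(tp.t2_lesion_mask & (tp.labels == BACKGROUND)):
                raise ValueError("lesion voxels must lie inside the brain")

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(tp.week for tp in self.timepoints)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.timepoints[0].labels.shape

    @property
    def baseline(self) -> Timepoint:
        return self.timepoints[0]

    def channel_volumes(self, name: str) -> list[np.ndarray]:
        return [tp.channel(name) for tp in self.timepoints]


@dataclass
class Cohort:
    config: PhantomConfig
    subjects: list[SubjectSeries]
    controls: dict[str, SubjectSeries]
    covariates: pd.DataFrame
    truth: pd.DataFrame
    extra_controls: list[SubjectSeries] = field(default_factory=list)

    @property
    def all_controls(self) -> list[SubjectSeries]:
        return list(self.controls.values()) + self.extra_controls


# ---------------------------------------------------------------------------
# template geometry


@dataclass
class Template:
    """Shared phantom geometry; identical for every subject of a config."""

    labels: np.ndarray
    brain: np.ndarray
    ventricles: np.ndarray
    ventricle_distance_mm: np.ndarray
    mtr_gradient: np.ndarray
    t2_texture: np.ndarray
    lesion_density: np.ndarray


def _mirror(volume: np.ndarray) -> np.ndarray:
    return np.flip(volume, axis=LR_AXIS)


def build_template(config: PhantomConfig) -> Template:
    """Construct the mirror-symmetric anatomical template.

    The template is built on one half-grid and reflected, so symmetry is
    bit-exact by construction rather than to floating-point tolerance.
    """
    shape = config.grid_shape
    spacing = np.asarray(config.voxel_size_mm, dtype=float)
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, spacing)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    extent = spacing * np.asarray(shape)

    a, b, c = 0.46 * extent[0], 0.46 * extent[1], 0.44 * extent[2]
    r = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    brain = r <= 1.0

    # Two mirrored periventricular CSF spaces; build right, reflect left.
    vx, vy, vz = 0.22 * a, 0.30 * b, 0.30 * c
    cx = 0.28 * a
    vent_right = (
        ((x - cx) / vx) ** 2 + (y / vy) ** 2 + (z / vz) ** 2
    ) <= 1.0
    ventricles = vent_right | _mirror(vent_right)
    ventricles &= brain
    if not ventricles.any() or not brain.any():
        raise ValueError(
            "grid too small to contain the ventricle template; enlarge "
            "grid_shape or shrink voxel_size_mm"
        )

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    labels[brain & (r > 0.80)] = GM
    labels[brain & (r <= 0.80)] = WM
    labels[ventricles] = CSF
    if not (labels == WM).any() or not (labels == GM).any():
        raise ValueError("grid too small: empty WM or GM compartment")

    dist = ndimage.distance_transform_edt(~ventricles, sampling=spacing)
    dist = np.minimum(dist, _mirror(dist))  # guard symmetry bit-exactly

    wm = labels == WM
    # Smooth periventricular-to-juxtacortical nMTR gradient, lowest near
    # the ventricles, with WM median pinned to zero so the WM median nMTR
    # stays exactly 1 after adding the gradient.
    grad = -np.exp(-dist / config.mtr_gradient_scale_mm)
    grad = config.mtr_gradient_amplitude * grad
    if config.mtr_gradient_amplitude != 0:
        grad = grad - np.median(grad[wm])
    grad[~wm] = 0.0

    # Deterministic smooth texture, even in the left-right coordinate so
    # mirror voxel pairs share the same value.
    tex = (
        np.cos(0.31 * x) * np.sin(0.27 * y)
        + np.cos(0.23 * z) * np.cos(0.17 * y)
        + 0.4 * np.cos(0.11 * x) * np.cos(0.13 * z + 0.4)
    )

    density = np.where(wm, np.exp(-dist / config.lesion_field_scale_mm), 0.0)

    return Template(
        labels=labels,
        brain=brain,
        ventricles=ventricles,
        ventricle_distance_mm=dist,
        mtr_gradient=grad,
        t2_texture=tex,
        lesion_density=density,
    )


# ---------------------------------------------------------------------------
# lesion placement


def _ellipsoid(shape, spacing, center, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    q = sum(
        (((g - c) * d) / rad) ** 2
        for g, c, d, rad in zip(grids, center, spacing, radii_mm)
    )
    return q <= 1.0


def _sample_events(
    config: PhantomConfig, template: Template, rng: np.random.Generator
) -> list[TruthEvent]:
    """Sample lesion events from the periventricular density field.

    Footprints are kept pairwise non-adjacent (2-voxel buffer, including
    their mirrors) so truth events remain in one-to-one correspondence
    with connected components recovered by the detector.
    """
    spacing = np.asarray(config.voxel_size_mm)
    density = template.lesion_density
    idx = np.flatnonzero(density)
    if idx.size == 0:
        return []
    p = density.ravel()[idx]
    p = p / p.sum()

    ramp = _effect_schedule(config)
    blocked = np.zeros(config.grid_shape, dtype=bool)
    events: list[TruthEvent] = []
    wm = template.labels == WM
    n_events = 0
    for week in config.visit_weeks[1:]:
        for _ in range(rng.poisson(config.lesion_rate)):
            placed = False
            for _attempt in range(config.max_placement_attempts):
                center = np.unravel_index(
                    rng.choice(idx, p=p), config.grid_shape
                )
                radii = rng.uniform(*config.lesion_radius_mm, size=3)
                ell = _ellipsoid(config.grid_shape, spacing, center, radii)
                if (ell & template.ventricles).any():
                    continue
                footprint = ell & wm
                mirror = _mirror(footprint)
                if footprint.sum() < 3:
                    continue
                if (footprint & mirror).any():
                    continue  # lesion straddling the midline
                if ((footprint | mirror) & blocked).any():
                    continue
                events.append(
                    TruthEvent(
                        lesion_id=f"L{n_events:03d}",
                        onset_week=int(week),
                        footprint=footprint,
                        mirror=mirror,
                        delta_nmtr=config.prelesion_delta_nmtr,
                        delta_nt2=config.prelesion_delta_nt2,
                        contralateral_fraction=config.contralateral_fraction,
                    )
                )
                n_events += 1
                blocked |= ndimage.binary_dilation(
                    footprint | mirror, structure=_STRUCT26, iterations=2
                )
                placed = True
                break
            if not placed:
                log.info(
                    "skipped one lesion at week %s after %d placement "
                    "attempts",
                    week,
                    config.max_placement_attempts,
                )
    return events


def _effect_schedule(config: PhantomConfig):
    """Return scale(week, onset_week) in [0, 1] for pre-lesion effects."""

    def scale(week: float, onset_week: float) -> float:
        if not config.onset_ramp:
            return 1.0
        lead = onset_week - week
        return float(max(0.0, 1.0 - lead / config.onset_ramp_weeks))

    return scale


# ---------------------------------------------------------------------------
# normalized-scale T2 injection

def _solve_t2_offsets(
    texture: np.ndarray,
    nawm: np.ndarray,
    overall: np.ndarray,
    footprints: Sequence[np.ndarray],
    mirrors: Sequence[np.ndarray],
    deltas: Sequence[float],
    contra_deltas: Sequence[float],
) -> np.ndarray:
    """Build the normalized T2 field with exact injected contrasts.

    Replaces the texture inside footprint j by a solved constant ``v_j``
    (and its mirror by ``u_j``) such that after standardizing the field
    over the baseline NAWM mask (exactly what the normalization stage
    does), the mean over *any subset* of footprint j minus the mean over
    overall NAWM equals ``deltas[j]`` and the mirror contrast equals
    ``contra_deltas[j]``.  Constant in-region values make the contrasts
    robust to downstream ROI trimming.  Regions are pairwise disjoint by
    construction of the placement.
    """
    g = texture
    n_m = int(nawm.sum())
    sum_g_m = float(g[nawm].sum())
    sumsq_g_m = float((g[nawm] ** 2).sum())
    n_o = int(overall.sum())
    sum_g_o = float(g[overall].sum())

    J = len(footprints)
    if J == 0:
        mu = sum_g_m / n_m
        sd = np.sqrt(max(sumsq_g_m / n_m - mu**2, 1e-30))
        return (g - mu) / sd

    n_f = np.array([m.sum() for m in footprints], dtype=float)
    sum_g_f = np.array([g[m].sum() for m in footprints])
    sumsq_g_f = np.array([(g[m] ** 2).sum() for m in footprints])
    sum_g_mf = np.array([g[m].sum() for m in mirrors])
    sumsq_g_mf = np.array([(g[m] ** 2).sum() for m in mirrors])
    # mirrors may intersect the overall-NAWM mask; footprints never do
    mf_in_o = [m & overall for m in mirrors]
    n_mf_in_o = np.array([float(m.sum()) for m in mf_in_o])
    sum_g_mf_in_o = np.array([float(g[m].sum()) for m in mf_in_o])
    deltas = np.asarray(deltas, dtype=float)
    contra = np.asarray(contra_deltas, dtype=float)

    def residual(vu: np.ndarray) -> np.ndarray:
        v, u = vu[:J], vu[J:]
        mean_m = (
            sum_g_m
            - sum_g_f.sum()
            - sum_g_mf.sum()
            + np.dot(v + u, n_f)
        ) / n_m
        meansq_m = (
            sumsq_g_m
            - sumsq_g_f.sum()
            - sumsq_g_mf.sum()
            + np.dot(v**2 + u**2, n_f)
        ) / n_m
        sd = np.sqrt(max(meansq_m - mean_m**2, 1e-30))
        mean_o = (
            sum_g_o - sum_g_mf_in_o.sum() + np.dot(u, n_mf_in_o)
        ) / n_o
        return np.concatenate(
            [
                (v - mean_o) / sd - deltas,
                (u - mean_o) / sd - contra,
            ]
        )

    x0 = np.concatenate(
        [sum_g_o / n_o + deltas, sum_g_o / n_o + contra]
    )
    sol, info, ier, msg = optimize.fsolve(
        residual, x0, full_output=True, xtol=1e-13
    )
    if ier != 1:
        raise RuntimeError(f"T2 injection solve failed: {msg}")

    u = g.astype(float).copy()
    for m, vj in zip(footprints, sol[:J]):
        u[m] = vj
    for m, uj in zip(mirrors, sol[J:]):
        u[m] = uj
    mu = u[nawm].mean()
    sd = u[nawm].std()
    return (u - mu) / sd


# ---------------------------------------------------------------------------
# scanner model


def _default_scanner_profiles(config: PhantomConfig) -> dict:
    """Per-scanner affine (gain, offset) per channel, seed-deterministic."""
    if config.scanner_profiles is not None:
        return config.scanner_profiles
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9021]))
    scales = {"mtr": MTR_WM - MTR_GM, "t1w": T1_WM - T1_GM, "t2w": T2_NAWM_SD}
    profiles = {}
    for sid in config.scanner_ids:
        profiles[sid] = {
            ch: (
                float(rng.uniform(0.9, 1.1)),
                float(rng.uniform(-0.5, 0.5) * scales[ch]),
            )
            for ch in CHANNELS
        }
    return profiles


def _channel_scale(channel: str) -> float:
    return {"mtr": MTR_WM - MTR_GM, "t1w": T1_WM - T1_GM, "t2w": T2_NAWM_SD}[
        channel
    ]


# ---------------------------------------------------------------------------
# subject generation


def _overall_nawm_for_truth(
    template: Template, events: Sequence[TruthEvent], spacing
) -> np.ndarray:
    """NAWM at all visits and >= 2 mm from any-time lesion voxels."""
    nawm_all = template.labels == WM
    union = np.zeros(template.labels.shape, dtype=bool)
    for ev in events:
        nawm_all = nawm_all & ~ev.footprint
        union |= ev.footprint
    if union.any():
        dist = ndimage.distance_transform_edt(~union, sampling=spacing)
        nawm_all &= dist >= 2.0
    return nawm_all


def _assemble_series(
    config: PhantomConfig,
    template: Template,
    events: list[TruthEvent],
    scanner_id: str,
    subject_id: str,
    rng: np.random.Generator,
    patient: bool = False,
) -> SubjectSeries:
    spacing = np.asarray(config.voxel_size_mm)
    profiles = _default_scanner_profiles(config)
    if scanner_id not in profiles:
        raise KeyError(f"unknown scanner_id {scanner_id!r}")
    profile = profiles[scanner_id]
    schedule = _effect_schedule(config)
    labels0 = template.labels
    nawm0 = labels0 == WM
    brain = template.brain
    overall = _overall_nawm_for_truth(template, events, spacing)

    ramped = config.onset_ramp and events
    if not ramped:
        h_static = _solve_t2_offsets(
            template.t2_texture,
            nawm0,
            overall,
            [ev.footprint for ev in events],
            [ev.mirror for ev in events],
            [ev.delta_nt2 for ev in events],
            [ev.contralateral_fraction * ev.delta_nt2 for ev in events],
        )

    timepoints = []
    for week in config.visit_weeks:
        active = [ev for ev in events if week >= ev.onset_week]
        pending = [ev for ev in events if week < ev.onset_week]

        labels = labels0.copy()
        lesion_mask = np.zeros(config.grid_shape, dtype=bool)
        for ev in active:
            labels[ev.footprint] = LESION
            lesion_mask |= ev.footprint

        # --- MTR: normalized-scale field, anchored at GM=0 / WM=1
        mtr_field = np.zeros(config.grid_shape)
        for lab, val in MTR_FIELD.items():
            mtr_field[labels0 == lab] = val
        mtr_field[nawm0] += template.mtr_gradient[nawm0]
        if patient and config.nawm_decrement_amplitude != 0.0:
            mtr_field[nawm0] -= (
                config.nawm_decrement_amplitude
                * template.lesion_density[nawm0]
            )
        for ev in pending:
            s = schedule(week, ev.onset_week)
            mtr_field[ev.footprint] -= s * ev.delta_nmtr
        for ev in events:
            s = schedule(week, ev.onset_week) if week < ev.onset_week else 1.0
            mtr_field[ev.mirror] -= (
                s * ev.contralateral_fraction * ev.delta_nmtr
            )
        mtr_field[labels == LESION] = MTR_FIELD[LESION]
        mtr = MTR_GM + (MTR_WM - MTR_GM) * mtr_field
        mtr[~brain] = 0.0

        # --- T1w: tissue-based field, no pre-lesion effect injected.
        # Within-tissue texture keeps the longitudinal LTS fit well-posed
        # (a piecewise-constant image admits spurious zero-residual fits
        # on single-tissue subsets).
        t1_field = np.zeros(config.grid_shape)
        for lab, val in T1_FIELD.items():
            t1_field[labels0 == lab] = val
        t1_field[labels == LESION] = T1_FIELD[LESION]
        t1_field[brain] += 0.05 * template.t2_texture[brain]
        t1w = T1_GM + (T1_WM - T1_GM) * t1_field
        t1w[~brain] = 0.0

        # --- T2w: standardized texture with exact injected contrasts
        if ramped:
            h = _solve_t2_offsets(
                template.t2_texture,
                nawm0,
                overall,
                [ev.footprint for ev in pending],
                [ev.mirror for ev in events],
                [schedule(week, ev.onset_week) * ev.delta_nt2 for ev in pending],
                [
                    (schedule(week, ev.onset_week) if week < ev.onset_week else 1.0)
                    * ev.contralateral_fraction
                    * ev.delta_nt2
                    for ev in events
                ],
            )
        else:
            h = h_static
        t2w = np.zeros(config.grid_shape)
        for lab, val in T2_BASE.items():
            t2w[labels0 == lab] = val
        t2w[brain] += T2_NAWM_SD * h[brain]
        t2w[labels == LESION] = T2_LESION
        t2w[~brain] = 0.0

        volumes = {"mtr": mtr, "t1w": t1w, "t2w": t2w}
        for ch in CHANNELS:
            gain, offset = profile[ch]
            v = gain * volumes[ch] + offset
            # per-visit acquisition drift; removed downstream by the
            # least-trimmed-squares longitudinal normalization (MTR is a
            # calibrated ratio and carries no drift)
            if ch in ("t1w", "t2w") and week != config.visit_weeks[0]:
                dg = 1.0 + config.drift_gain_sd * rng.standard_normal()
                do = (
                    config.drift_offset_sd
                    * _channel_scale(ch)
                    * rng.standard_normal()
                )
                v = dg * v + do
            if config.noise_sd > 0:
                v = v + config.noise_sd * _channel_scale(ch) * (
                    rng.standard_normal(config.grid_shape)
                )
            volumes[ch] = v

        timepoints.append(
            Timepoint(
                week=int(week),
                mtr=volumes["mtr"],
                t1w=volumes["t1w"],
                t2w=volumes["t2w"],
                labels=labels,
                t2_lesion_mask=lesion_mask,
            )
        )

    return SubjectSeries(
        subject_id=subject_id,
        scanner_id=scanner_id,
        voxel_size_mm=config.voxel_size_mm,
        timepoints=timepoints,
        truth=events,
    )


def generate_healthy_control(
    config: PhantomConfig,
    scanner_id: str,
    seed: int,
    subject_id: str = "hc",
    template: Template | None = None,
) -> SubjectSeries:
    """Generate a lesion-free, mirror-symmetric control series."""
    rng = np.random.default_rng(seed)
    tpl = template if template is not None else build_template(config)
    return _assemble_series(config, tpl, [], scanner_id, subject_id, rng)


def generate_ms_subject(
    config: PhantomConfig,
    scanner_id: str,
    seed: int,
    subject_id: str = "sub",
    template: Template | None = None,
) -> SubjectSeries:
    """Generate a subject with scheduled lesion events and pre-lesion
    abnormalities injected on the normalized scales."""
    rng = np.random.default_rng(seed)
    tpl = template if template is not None else build_template(config)
    events = _sample_events(config, tpl, rng)
    return _assemble_series(
        config, tpl, events, scanner_id, subject_id, rng, patient=True
    )


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.round(rng.uniform(25.0, 55.0), 1)),
        "sex": "F" if rng.random() < 0.6 else "M",
        "treatment_group": "active" if rng.random() < 0.5 else "placebo",
        "disease_duration": float(np.round(rng.uniform(0.5, 15.0), 1)),
        "baseline_gd_count": int(rng.poisson(1.0)),
        "baseline_t2_volume": float(np.round(rng.lognormal(8.0, 0.8), 1)),
    }


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate the full cohort: patients, one control per scanner plus
    extras for atlas building, the covariate table and the truth ledger."""
    ss = np.random.SeedSequence(config.seed)
    template = build_template(config)
    scanner_ids = config.scanner_ids
    n_controls = (
        config.n_controls if config.n_controls is not None else len(scanner_ids)
    )
    n_controls = max(n_controls, len(scanner_ids))

    child_seeds = ss.spawn(config.n_subjects + n_controls + 1)
    cov_rng = np.random.default_rng(child_seeds[-1])

    controls: dict[str, SubjectSeries] = {}
    extra_controls: list[SubjectSeries] = []
    for i in range(n_controls):
        sid = scanner_ids[i % len(scanner_ids)]
        hc = generate_healthy_control(
            config,
            sid,
            child_seeds[config.n_subjects + i],
            subject_id=f"hc-{i:03d}",
            template=template,
        )
        if sid not in controls:
            controls[sid] = hc
        else:
            extra_controls.append(hc)

    subjects: list[SubjectSeries] = []
    cov_rows = []
    truth_rows = []
    for i in range(config.n_subjects):
        sid = scanner_ids[i % len(scanner_ids)]
        sub = generate_ms_subject(
            config,
            sid,
            child_seeds[i],
            subject_id=f"sub-{i:03d}",
            template=template,
        )
        sub.covariates = _draw_covariates(cov_rng)
        subjects.append(sub)
        cov_rows.append(
            {"subject_id": sub.subject_id, "scanner_id": sid, **sub.covariates}
        )
        for ev in sub.truth:
            center = np.array(np.nonzero(ev.footprint)).mean(axis=1)
            truth_rows.append(
                {
                    "subject_id": sub.subject_id,
                    "lesion_id": ev.lesion_id,
                    "onset_week": ev.onset_week,
                    "n_voxels": ev.n_voxels,
                    "volume_mm3": ev.n_voxels * config.voxel_volume_mm3,
                    "delta_nmtr": ev.delta_nmtr,
                    "delta_nt2": ev.delta_nt2,
                    "contralateral_fraction": ev.contralateral_fraction,
                    "center_i": center[0],
                    "center_j": center[1],
                    "center_k": center[2],
                }
            )

    return Cohort(
        config=config,
        subjects=subjects,
        controls=controls,
        covariates=pd.DataFrame(
            cov_rows,
            columns=[
                "subject_id",
                "scanner_id",
                "age",
                "sex",
                "treatment_group",
                "disease_duration",
                "baseline_gd_count",
                "baseline_t2_volume",
            ],
        ),
        truth=pd.DataFrame(
            truth_rows,
            columns=[
                "subject_id",
                "lesion_id",
                "onset_week",
                "n_voxels",
                "volume_mm3",
                "delta_nmtr",
                "delta_nt2",
                "contralateral_fraction",
                "center_i",
                "center_j",
                "center_k",
            ],
        ),
        extra_controls=extra_controls,
    )
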