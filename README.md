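# prelesion

Backward analysis of normal-appearing white matter (NAWM) before new T2
lesion formation, packaged as a tested, reusable pipeline exercised
end-to-end on synthetic longitudinal MRI cohorts:

- **`prelesion.cohort`** — synthetic cohort generator: mirror-symmetric
  brain phantoms (GM/WM/CSF ventricles), a periventricular lesion
  density field, scheduled new-lesion events, scanner-specific affine
  intensity distortion and per-visit drift, and configurable pre-lesion
  nMTR decrements / nT2 increments injected on the *normalized* scales
  so the full pipeline recovers them exactly on noiseless data.
- **`prelesion.normalize`** — the three intensity-normalization schemes:
  scanner-calibrated nMTR (healthy GM → 0, healthy WM → 1), two-stage
  nT1 (tissue-based map + least-trimmed-squares longitudinal alignment)
  and two-stage nT2 (LTS alignment + NAWM z-scoring), including the LTS
  estimator itself (C-steps, multi-start, deterministic under seed).
- **`prelesion.lesions`** — new-T2-lesion detection between consecutive
  visits (26-connectivity, enlargement exclusion) and longitudinal
  tracking to the end-of-study residual mask.
- **`prelesion.rois`** — overall-NAWM, pre-lesion and mirror-matched
  contralateral ROIs under the selection rules (≥ 10 voxels, NAWM at all
  relevant visits, ≥ 2 mm exact anisotropic Euclidean distance from
  lesions, mirror reconciliation).
- **`prelesion.stats`** — the long-format contrast table (pre vs
  overall, pre vs contralateral, contralateral vs overall) and a
  patient-weighted linear mixed-effects model with a random lesion
  effect nested in a random patient effect and AR(1) residual
  correlation, fitted by profiled REML; least-square means per
  time-before-onset with Holm/Bonferroni adjustment.
- **`prelesion.atlas`** — voxel-wise mean-nMTR atlases, HC − PwMS
  difference atlas, T2 lesion probability atlas, categorical probability
  bins, the likelihood-ratio linear-trend test and ROI-by-bin frequency
  distributions.
- **`prelesion.pipeline` / `prelesion.cli`** — orchestration with
  reproducible configuration (config hash stamped into every output
  table).

## CLI

```sh
prelesion run -c config.yaml -o out/          # full pipeline
prelesion simulate -c config.yaml -o cohort/  # write a cohort (NIfTI+TSV)
prelesion normalize -i cohort/ -o norm/       # nMTR / nT1 / nT2 volumes
prelesion track     -i cohort/ -o events/     # new-lesion event table
prelesion rois      -i cohort/ -o rois/       # ROI masks + QC ledger
prelesion stats     -i cohort/ -o stats/      # sample table + LS means
prelesion atlas     -i cohort/ -o atlas/      # atlases, bins, trend test
```

A minimal `config.yaml`:

```yaml
trial_mode: synergy_monthly   # or ascend_semiannual / advance_annual
phantom:
  n_subjects: 8
  lesion_rate: 0.5
  prelesion_delta_nmtr: 0.2   # injected nMTR decrement
  prelesion_delta_nt2: 0.3    # injected nT2 increment (NAWM-SD units)
  contralateral_fraction: 0.3
  noise_sd: 0.02
  seed: 1
covariates: [age, sex]
```

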