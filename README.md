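# dualphase-pet

Analysis toolkit for **dual-phase dynamic SV2A PET** in focal epilepsy —
the imaging idea that a single dynamic scan with an SV2A tracer (such as
[¹⁸F]UCB-H) carries two complementary signals: an **early post-injection
phase (0–10 min)** that behaves like a perfusion map and tracks
[¹⁸F]FDG-style metabolic images, and a **late phase (30–60 min)** that
reflects synaptic density and delineates epileptogenic lesions with high
contrast. The package is aimed at PET methodologists who want to exercise,
test and extend the full analysis chain without patient data: every input
is produced by a synthetic cohort generator with known ground truth.

## What it implements

- **Synthetic cohort generator** (`phantom_sim`) — an exactly
  mirror-symmetric geometric brain phantom (32 regions, including ≥10
  cortical subregions per hemisphere, white-matter centrum semiovale,
  cerebellum, pons and a vascular blood pool), one-tissue-compartment
  kinetics `CT(t) = K1 ∫ Cp(τ) e^{−k2(t−τ)} dτ` driven by a parametric
  plasma input function, pharmacologic target blockade as occupancy of the
  specific binding fraction (k₂ → k₂/(1 − occ·f_s), so V_T scales down
  while first-pass influx K₁·Cp is untouched), unilateral lesions with a
  confined synaptic-loss core inside a broader hypoperfusion zone, PSF
  blurring to the intrinsic scanner resolution (6.6 × 6.6 × 5.1 mm), and
  frame-duration-scaled noise correlated at that resolution.
- **Imaging core** (`imaging_core`) — frame-schedule arithmetic
  (`"12x5,6x10,3x20,7x60,4x300,3x600"` → 35 contiguous frames over
  60 min), SUV conversion, duration-weighted window averaging, SUVR with
  selectable reference regions, NIfTI I/O (nibabel).
- **TAC analysis** (`tac_analysis`) — regional time–activity curves, peak
  characterization, Welch t-tests of blocked vs unblocked arms per region
  and window with Holm–Šidák adjustment.
- **Cross-tracer window selection** (`crosstracer`) — framewise Pearson
  correlation between dynamic-tracer frames and static FDG-like uptake
  across subjects, within-subject regional correlations, and selection of
  imaging windows as maximal runs of consecutively significant frames.
- **Asymmetry lesion mapping** (`asymmetry`) — smooth → flip across the
  midsagittal plane → voxelwise percent difference against the mirrored
  hemisphere → cortical masking → −8 % threshold → retain the most
  affected 90 % of suprathreshold voxels → severity (mean Δ%) and volume
  (mL); kernel sweeps of lesion signal vs background noise; Gaussian
  resolution arithmetic (FWHM in quadrature: 6.6 ⊕ 8 → 10.4 mm).
- **Graphical kinetics** (`kinetics`) — Logan V_T from an image-derived
  input function, reference-tissue Logan DVR with k₂-reference
  correction, and agreement of late-window SUVR with V_T ratios and DVR.
- **Statistics & reporting** (`stats_report`) — Holm–Šidák step-down,
  one-way ANOVA + Tukey HSD, and the cross-modality severity/volume
  comparison tables.
- **Pipeline + CLI** (`pipeline`, `dualphase-pet`) — one-config
  orchestration with per-subject RNG streams and a hashed, bit-reproducible
  artifact manifest.

## Worked example

```python
from dualphase_pet import CohortConfig, generate_cohort, compare_groups
from dualphase_pet.asymmetry import analyze_lesion
from dualphase_pet.phantom_sim import cortex_labels

config = CohortConfig(grid_shape=(48, 48, 40), voxel_size_mm=(4, 4, 4))
cohort = generate_cohort(config, seed=1)   # 21 unblocked + 8 blocked subjects

table = cohort.tac_table_suv
rois = ["cerebral_cortex", "thalamus_left", "centrum_semiovale_left"]
print(compare_groups(table[table["region"].isin(rois)]).round(4).to_string(index=False))

subject = cohort.subjects[0]
late = cohort.render_window(subject, 1800, 3600)
_, _, metrics = analyze_lesion(
    late, cohort.labels, subject.lesion.side, 8.0, cortex_labels(cohort.phantom_spec)
)
print(f"{subject.subject_id}: severity {metrics.severity_pct:.1f}%, "
      f"volume {metrics.volume_mL:.1f} mL")
```

prints

```
                region window  mean_unblocked  mean_blocked  percent_change  raw_p  adjusted_p
centrum_semiovale_left  early          3.0809        2.4902        -19.1728 0.1818      0.2413
       cerebral_cortex  early          6.4609        5.0182        -22.3293 0.1289      0.2413
         thalamus_left  early          6.8748        4.8511        -29.4373 0.0317      0.0922
centrum_semiovale_left   late          1.4558        1.2153        -16.5210 0.2600      0.2600
       cerebral_cortex   late          3.6719        1.8788        -48.8320 0.0024      0.0070
         thalamus_left   late          3.1406        1.7290        -44.9475 0.0049      0.0097

sub-001: severity -15.5%, volume 11.5 mL
```

Reading this: SV2A-binding medication halves the late-window cortical
signal (−48.8 %, adjusted p = 0.007) while the early window shows no
significant group difference and the white-matter reference region is
insensitive — the blockade pattern the dual-phase design relies on. The
late-phase asymmetry analysis localizes the subject's simulated lesion;
the recovered depth is attenuated by partial-volume averaging at this
lesion size (see `docs/methods.md`).

The same chain runs from the shell:

```bash
dualphase-pet all --out results/demo --seed 1
dualphase-pet report --in results/demo
```

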