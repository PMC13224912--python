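# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Kinetic model

All tissue curves follow a one-tissue compartment (1TC) model,

    dCT/dt = K1·Cp(t) − k2·CT(t),    VT = K1/k2,

with `K1` in mL·cm⁻³·min⁻¹ and `k2` in min⁻¹. A 1TC description is
sufficient for the package's purposes: it reproduces the qualitative
dual-phase phenomenology (rapid influx, peak within minutes, continuous
washout; earlier peaks and faster washout under blockade) and makes Logan
graphical recovery exact in the noise-free limit, which gives the kinetics
module a closed-form oracle (`VT = K1/k2`).

**Blockade.** SV2A-binding medication removes the specific (displaceable)
part of the distribution volume. With specific fraction `f_s` per region
and occupancy `o`, the effective efflux is `k2/(1 − o·f_s)`, so
`VT → VT·(1 − o·f_s)` while the first-pass influx term `K1·Cp` is exactly
unchanged — by construction early-phase signal is insensitive to
blockade, up to the small washout that occurs inside the first minute.
That residual is real physics, not an artifact: with tracer arriving
~35 s into a 60-s window, the mean washout exposure times the k₂ increase
yields a ~3 % first-pass change at occupancy 0.8 (tested: < 2 % up to
occupancy 0.6, < 4 % at 0.8). The centrum semiovale is assigned
`f_s = 0.1` (90 % nondisplaceable), making it blockade-insensitive and
suitable as a late-phase reference region; cortical regions use
`f_s ≈ 0.84–0.95`, which also makes blockade distort the regional
pattern — the reason within-subject late-phase agreement with the static
tracer degrades in blocked subjects.

**Input function.** A gamma-variate bolus `(t/tp)^α e^{α(1−t/tp)}`
(`tp = 30 s`, `α = 3`) plus a biexponential tail (fractions 0.12 / 0.035
of the bolus amplitude, rate constants 1/90 s⁻¹ and 1/2400 s⁻¹), smoothly
switched on over the bolus rise so `Cp(0) = 0` with a single early peak
and a monotone tail. The tail fractions were chosen so that a cortical
region with `K1 = 0.25`, `VT = 5` peaks near 4 min — the unblocked study
condition. The integrator is an exponential-integrator recursion (exact
for piecewise-linear Cp), evaluated as an IIR filter; frame values are
duration averages via cumulative trapezoid. A brute-force discrete
convolution oracle on a 0.1-s grid agrees within 0.5 %.

## Phantom and cohort generator

The phantom is a geometric, exactly mirror-symmetric label volume:
regions are defined analytically in millimetres about the grid centre and
painted onto any grid (default 96×96×80 at 2 mm; tests use 48×48×40 at
4 mm, same field of view). Axis 0 is left–right; for even grids the
midplane lies between voxel columns, so `flip(axis=0)` is an exact mirror.
A supratentorial ellipsoid's outer shell (normalized radius 0.72–1.0)
splits into 10 angular cortical sectors per hemisphere; paired temporal,
basal-ganglia, thalamus, centrum-semiovale and cerebellum regions, a
midline pons and a vascular blood pool complete 32 labels. Overlapping
region definitions are a hard error. Regional `K1`, `VT`, `f_s` and FDG
uptake baselines are free parameters of the generator (the study
conditions pin only the cortical peak statistics); they are documented in
`phantom_sim._BASE_KINETICS` and vary mildly across cortical sectors so
that rank-order and regional-correlation analyses are non-degenerate.

**Study conditions.** Cohorts default to 21 unblocked + 8 blocked
subjects. Per subject, a cortical peak time and peak SUV are drawn from
the arm-specific distributions (unblocked 7.4 ± 1.6 SUV at 4.0 ± 0.7 min;
blocked 6.4 ± 2.3 at 2.7 ± 0.8 min), injected activities from
185.1 ± 13.6 MBq (SV2A) and 146.7 ± 10.5 MBq (FDG), body weight
75 ± 12 kg. The drawn peak time is imposed by solving (Brent) for a
global washout scale; for blocked subjects a counterfactual unblocked
washout is drawn first and the occupancy producing the earlier blocked
peak is solved on top of it, so occupancy — recorded in the truth table —
carries exactly the blocked-minus-unblocked kinetic difference. The drawn
peak SUV is imposed by scaling the input-function amplitude. Biological
between-subject variation enters as log-normal jitter on regional `K1`
(shared with FDG uptake, giving the early-phase cross-tracer coupling)
and independent jitter on regional `VT` (decoupling late-phase binding),
drawn once per left–right region *pair* so the lesion-free brain stays
hemispherically symmetric.

**Lesions.** Each subject receives one unilateral lesion centred on a
cortical sector: a core of drawn radius (14 ± 3 mm) with synaptic loss,
inside a broader zone of independently drawn radius (28 ± 5 mm) carrying
the perfusion/metabolic deficit (K₁ reduced by the drawn perfusion
fraction, 0.20 ± 0.04; FDG uptake reduced by the drawn FDG severity,
0.20 ± 0.04). Core severity (0.25 ± 0.05) is defined *operationally* as
the noise-free late-window (30–60 min) signal reduction; the
distribution-volume scale that produces exactly that reduction — given
the lesioned K₁ and the subject's input function — is solved for
numerically. A naive `VT·(1−severity)` scaling would miss the target by
several points because the plasma tail decays on a timescale comparable
to 1/k₂, so the late window is not at true equilibrium. The broad zone's
late reduction is calibrated to 4 %, below the 8 % asymmetry threshold:
hypoperfused but synaptically intact tissue, which is what confines the
late-phase lesion relative to the early-phase and FDG lesions. Lesion
intensity draws share a latent factor (ρ = 0.7) across modalities, while
the two radii are independent — producing correlated severities and
correlated FDG/early volumes with an uncorrelated late volume.

**Rendering and noise.** Per frame, regional values are painted, blurred
with a Gaussian PSF at the intrinsic resolution (6.6 × 6.6 × 5.1 mm
FWHM), and noise is added with SD `noise_scale·sqrt(max(C, ε)/Δt)` —
the 1/√(frame duration) behaviour of reconstructed PET. The noise field
is white noise convolved with the same PSF and rescaled to the target SD
(the attenuation factor is computed exactly from the discrete kernels),
i.e. noise is correlated at the intrinsic resolution, as in reconstructed
images; a `noise_correlation="white"` mode exists. `noise_scale = 2`
(kBq/mL·√s units) gives late-window background asymmetry SDs of a few
percent on the default grid. TAC-level tables (used by the group and
correlation analyses without rendering volumes) receive the matching
regional noise, reduced by the effective number of PSF-sized resolution
cells per region.

## Analysis chain

- **Windows**: frames fully contained in the window, duration-weighted
  (the 0–10 and 30–60 min windows align with frame boundaries of the
  35-frame schedule, so partial-frame weighting is unnecessary). TAC time
  coordinate = frame midpoint.
- **SUV** uses the g/mL convention; **SUVR** divides by the mean over the
  reference-region labels (cerebellum for early phase, centrum semiovale
  for late, pons and whole-brain global mean as alternates).
- **Group comparison**: Welch t-test by default (arms of 21 vs 8 with
  unequal variances; a pooled flag exists), Holm–Šidák adjusted across
  regions within each window, at ROI level (cortical sectors enter via
  the voxel-weighted composite cortex). Peaks are computed per subject
  and then summarized.
- **Framewise correlation**: Pearson r with the two-sided t-based
  p-value; α = 0.05 uncorrected along frames; windows are maximal runs of
  ≥ 3 consecutively significant frames (min_run suppresses single-frame
  noise), reported as [start of first frame, end of last frame].
- **Asymmetry**: smoothing is applied before flipping; Δ% divides by the
  mirrored (contralateral) value — a symmetric-mean denominator variant
  makes side-swapping an exact negation and is available as an option.
  Denominator guard ε = 1 % of the image's 99th percentile; guarded
  voxels are dropped from the mask and counted. Lesion polarity is
  hypo-signal only (Δ% ≤ −threshold). The "most affected 90 %" keeps the
  90 % of suprathreshold voxels with largest |Δ%| (by-count retention,
  magnitude ranking, ties by voxel index). Background noise for kernel
  sweeps is the SD of Δ% over the contralateral cortical mask — the only
  lesion-free cortical compartment by construction.
- **Kinetics**: Logan VT regresses ∫CT/CT on ∫Cp/CT past t* = 15 min
  (default; well past the ~4-min cortical peak), trapezoidal integrals on
  frame midpoints, the plasma integral on the input function's fine grid.
  Reference Logan DVR adds the Cref/k₂-ref correction; k₂-ref comes from
  generator truth in tests and from configuration in runs. The IDIF is
  the blood-pool TAC interpolated to a fine grid.

## Numerical choices and degenerate inputs

Zero-variance vectors are errors in correlation (distinct from r = 0);
groups below 2 subjects, empty masks, missing labels, windows without a
complete frame, non-contiguous schedules and t* beyond the scan are all
hard errors naming the offending quantity. Identical ANOVA groups return
F = 0, p = 1 by convention. Holm–Šidák clips into [0, 1] and enforces
`adjusted ≥ raw` exactly against float rounding. All randomness flows
from `numpy.random.default_rng` with per-subject streams seeded by
(master seed, subject index, stage), so truth tables are invariant under
cohort-size changes and pipeline reruns are bit-identical.

## Problem sizes

The default generator grid is 96×96×80 at 2 mm (< 1 min per rendered
subject on a laptop core). The test suite and pipeline demonstrations use
the same field of view at 4 mm (48×48×40) with cohorts of 6–29 subjects at
TAC level and ≤ 6 rendered subjects, which keeps the full suite around
ten seconds; the smoothing noise-reduction simulation runs on the 2-mm
grid with 10 noise seeds as its averaging conditions.

## What passing tests do and do not show

The generator emulates frame-timing, PSF, duration-scaled correlated
noise, blockade kinetics and compound lesions, but not anatomy
(geometric regions, no MRI template), scatter/attenuation, motion,
misregistration, decay correction, or arterial sampling beyond the
parametric Cp. Recovery results therefore demonstrate the correctness and
calibration of the *analysis chain* under its stated model, not clinical
performance. Known quantitative caveats:

- The mean-Δ% severity estimator is diluted by the boundary transition
  zone: with the standard 8-mm kernel on a ~24-mm lesion the recovered
  depth sits at ~80–90 % of truth; recovery within ±3 points holds when
  the kernel is small relative to the lesion (tested at 4 mm / 24 mm).
  The 90 %-retention rule bounds edge noise but not this bias.
- Late-window reductions under blockade slightly exceed `o·f_s` because
  the window is not at true equilibrium (same mechanism as the lesion
  calibration); group percent changes are therefore pattern-level
  quantities, not occupancy estimates.
- With an arm of 8 subjects and the specified peak-SUV variability, SUV
  group comparisons in blockade-insensitive regions fluctuate by tens of
  percent without reaching significance; insensitivity claims are
  statistical, not point bounds.
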