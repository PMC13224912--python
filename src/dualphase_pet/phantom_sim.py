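"""Synthetic paired dynamic SV2A-like and static FDG-like brain cohorts.

A geometric, exactly mirror-symmetric label phantom stands in for an
anatomical atlas: a supratentorial ellipsoid whose outer shell is split
into 10 cortical sectors per hemisphere, plus paired temporal, basal
ganglia, thalamus, centrum semiovale and cerebellum regions, a midline
pons and a vascular blood pool (32 labels, emulating a multi-region
anatomical parcellation). Regional kinetics follow a one-tissue
compartment model driven by a parametric plasma input function; target
blockade by SV2A-binding medication is modelled as occupancy of the
specific (displaceable) fraction of the distribution volume, which
inflates the efflux rate while leaving first-pass influx unchanged.
Unilateral lesions combine a confined synaptic-loss core (calibrated
late-phase reduction) with a broader hypoperfusion/hypometabolism zone.
Rendering blurs painted regional values with the intrinsic scanner PSF
and adds frame-duration-scaled noise correlated at that resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, signal

from .asymmetry import fwhm_to_sigma, gaussian_smooth
from .imaging_core import (
    DynamicImage,
    FrameSchedule,
    StaticImage,
    ReferenceRegion,
    parse_frame_spec,
    write_dynamic_nifti,
    write_label_nifti,
    write_static_nifti,
)
from .tac_analysis import TimeActivityCurve

__all__ = [
    "RegionDef",
    "PhantomSpec",
    "KineticParams",
    "LesionSpec",
    "InputFunction",
    "default_phantom_spec",
    "build_phantom",
    "mirror_labels",
    "cortex_labels",
    "reference_region",
    "parametric_input_function",
    "simulate_tac",
    "render_dynamic_image",
    "render_static_fdg",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Phantom geometry


@dataclass(frozen=True)
class RegionDef:
    """One atlas region: a geometric primitive with a label and a side."""

    label: int
    name: str
    side: str  # left | right | midline
    kind: str  # sphere | ellipsoid | cortex_sector
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "midline"):
            raise ValueError(f"bad side {self.side!r} for region {self.name!r}")
        if self.label <= 0:
            raise ValueError("labels must be positive integers")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus the region list of the symmetric template."""

    grid_shape: tuple[int, int, int] = (96, 96, 80)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: tuple[RegionDef, ...] = ()

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")

    @property
    def region_by_label(self) -> dict[int, RegionDef]:
        return {r.label: r for r in self.regions}

    @property
    def label_by_name(self) -> dict[str, int]:
        return {r.name: r.label for r in self.regions}

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates in mm relative to the grid center.

        Axis 0 is left-right; the midsagittal plane is x = 0 (between voxel
        columns for an even grid, on a column for an odd grid).
        """
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.grid_shape, self.voxel_size_mm)
        ]
        return np.meshgrid(*axes, indexing="ij")


# geometry constants (mm): a supratentorial ellipsoid with a cortical shell,
# an inferior-posterior fossa (cerebellum + pons) excluded from the shell
_SUPRA_CENTER = (0.0, 8.0, 10.0)
_SUPRA_RADII = (70.0, 75.0, 55.0)
_RHO_INNER = 0.72
_FOSSA_Y_MAX = -25.0  # shell voxels with y < this AND z < _FOSSA_Z_MAX excluded
_FOSSA_Z_MAX = -22.0
_TEMPORAL = ((50.0, -14.0, -20.0), 15.0)
_N_CORTEX_SECTORS = 10


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = (96, 96, 80),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PhantomSpec:
    """The standard symmetric phantom (geometry fixed in mm, grid free)."""
    regions: list[RegionDef] = []

    def paired(base_label: int, name: str, kind: str, center, *rest) -> None:
        cx, cy, cz = center
        regions.append(
            RegionDef(base_label, f"{name}_left", "left", kind, ((-cx, cy, cz),) + rest)
        )
        regions.append(
            RegionDef(base_label + 1, f"{name}_right", "right", kind, ((cx, cy, cz),) + rest)
        )

    paired(1, "temporal", "sphere", *_TEMPORAL)
    paired(3, "basal_ganglia", "sphere", (28.0, 12.0, 2.0), 14.0)
    paired(5, "thalamus", "sphere", (11.0, -10.0, 0.0), 10.0)
    paired(7, "centrum_semiovale", "ellipsoid", (26.0, 6.0, 28.0), (16.0, 28.0, 10.0))
    paired(9, "cerebellum", "sphere", (18.0, -54.0, -40.0), 16.0)
    regions.append(RegionDef(11, "pons", "midline", "sphere", ((0.0, -34.0, -36.0), 8.0)))
    regions.append(RegionDef(12, "blood_pool", "midline", "sphere", ((0.0, 20.0, -10.0), 8.0)))

    for i in range(_N_CORTEX_SECTORS):
        regions.append(
            RegionDef(101 + i, f"cortex_L{i + 1:02d}", "left", "cortex_sector", (i,))
        )
        regions.append(
            RegionDef(201 + i, f"cortex_R{i + 1:02d}", "right", "cortex_sector", (i,))
        )
    return PhantomSpec(tuple(grid_shape), tuple(voxel_size_mm), tuple(regions))


def _region_mask(
    region: RegionDef,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    x, y, z = coords
    if region.kind == "sphere":
        (cx, cy, cz), r = region.params
        mask = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < r**2
    elif region.kind == "ellipsoid":
        (cx, cy, cz), (rx, ry, rz) = region.params
        mask = (
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 < 1.0
        )
    elif region.kind == "cortex_sector":
        (sector,) = region.params
        cx, cy, cz = _SUPRA_CENTER
        rx, ry, rz = _SUPRA_RADII
        rho2 = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        shell = (rho2 >= _RHO_INNER**2) & (rho2 < 1.0)
        shell &= ~((y < _FOSSA_Y_MAX) & (z < _FOSSA_Z_MAX))
        (tx, ty, tz), tr = _TEMPORAL
        for sx in (-1.0, 1.0):
            shell &= (x - sx * tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2 >= tr**2
        theta = np.arctan2(z - cz, y - cy)
        idx = np.clip(
            ((theta + np.pi) / (2 * np.pi / _N_CORTEX_SECTORS)).astype(int),
            0,
            _N_CORTEX_SECTORS - 1,
        )
        mask = shell & (idx == sector)
    else:
        raise ValueError(f"unknown region kind {region.kind!r}")

    if region.side == "left":
        mask &= x < 0
    elif region.side == "right":
        mask &= x > 0
    return mask


def build_phantom(spec: PhantomSpec) -> np.ndarray:
    """Paint the integer label volume; raises on overlapping regions."""
    coords = spec.coordinates_mm()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for region in spec.regions:
        mask = _region_mask(region, coords)
        clash = mask & (labels != 0)
        if clash.any():
            other = int(labels[clash][0])
            other_name = spec.region_by_label[other].name
            raise ValueError(
                f"regions overlap: {region.name!r} (label {region.label}) and "
                f"{other_name!r} (label {other})"
            )
        labels[mask] = region.label
    return labels


def mirror_label_table(spec: PhantomSpec) -> dict[int, int]:
    """label -> label of the mirror-image region (midline maps to itself)."""
    by_name = spec.label_by_name
    table: dict[int, int] = {0: 0}
    for r in spec.regions:
        if r.side == "midline":
            table[r.label] = r.label
        elif r.side == "left":
            partner = r.name.replace("_left", "_right").replace("_L", "_R")
            table[r.label] = by_name[partner]
        else:
            partner = r.name.replace("_right", "_left").replace("_R", "_L")
            table[r.label] = by_name[partner]
    return table


def mirror_labels(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Flip across the midplane and swap left/right labels."""
    table = mirror_label_table(spec)
    lut = np.zeros(max(table) + 1, dtype=labels.dtype)
    for k, v in table.items():
        lut[k] = v
    return lut[np.flip(labels, axis=0)]


def cortex_labels(spec: PhantomSpec) -> dict[str, set[int]]:
    """Cortical label sets per hemisphere (the shell sectors)."""
    out: dict[str, set[int]] = {"left": set(), "right": set()}
    for r in spec.regions:
        if r.kind == "cortex_sector":
            out[r.side].add(r.label)
    return out


_REFERENCE_NAMES = ("cerebellum", "centrum_semiovale", "pons", "whole_brain_global_mean")


def reference_region(spec: PhantomSpec, name: str) -> ReferenceRegion:
    """Resolve a named reference region to its atlas labels."""
    if name not in _REFERENCE_NAMES:
        raise ValueError(f"unknown reference region {name!r}; use one of {_REFERENCE_NAMES}")
    if name == "whole_brain_global_mean":
        labels = {r.label for r in spec.regions if r.name != "blood_pool"}
    else:
        labels = {r.label for r in spec.regions if r.name.startswith(name)}
    return ReferenceRegion(name, frozenset(labels))


# ---------------------------------------------------------------------------
# Kinetics


@dataclass(frozen=True)
class KineticParams:
    """One-tissue-compartment parameters for a region.

    VT = K1/k2. Blockade occupancy removes the specific (displaceable)
    fraction of VT: the effective efflux rate is
    ``k2 / (1 - occupancy * specific_fraction)``, so VT scales down while
    the first-pass influx K1*Cp is unchanged.
    """

    K1: float  # mL/cm^3/min
    k2: float  # 1/min
    specific_fraction: float = 0.9
    occupancy: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError(f"K1 must be >= 0, got {self.K1}")
        if self.k2 <= 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValueError("specific_fraction must lie in [0, 1]")
        if not 0.0 <= self.occupancy < 1.0:
            raise ValueError("occupancy must lie in [0, 1)")

    @property
    def VT(self) -> float:
        return self.K1 / self.k2

    @property
    def k2_effective(self) -> float:
        return self.k2 / (1.0 - self.occupancy * self.specific_fraction)

    @property
    def VT_effective(self) -> float:
        return self.K1 / self.k2_effective


@dataclass(frozen=True)
class InputFunction:
    """Plasma activity Cp(t) in kBq/mL on a uniform fine time grid."""

    t_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("t_s and values must be matching 1D arrays")
        dt = np.diff(t)
        if t[0] != 0.0 or not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform and start at 0")
        if np.any(v < 0):
            raise ValueError("Cp must be non-negative")
        if v[0] != 0.0:
            raise ValueError("Cp(0) must be 0")

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    def scaled(self, factor: float) -> "InputFunction":
        return InputFunction(self.t_s, self.values * factor)

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        return _frame_averages(self.values, self.t_s, schedule)


def parametric_input_function(
    duration_s: float = 3900.0,
    dt_s: float = 0.1,
    amplitude_kBq_mL: float = 40.0,
    t_peak_s: float = 30.0,
    alpha: float = 3.0,
    tail_fracs: tuple[float, float] = (0.12, 0.035),
    tail_lambdas_per_s: tuple[float, float] = (1.0 / 90.0, 1.0 / 2400.0),
) -> InputFunction:
    """Gamma-variate bolus plus biexponential tail.

    The bolus term ``(t/tp)^alpha * exp(alpha*(1 - t/tp))`` peaks at unity
    at `t_peak_s`; the tail is switched on smoothly over the bolus rise so
    Cp(0) = 0 and the curve has a single early peak followed by a
    monotonically decaying tail.
    """
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    tp = float(t_peak_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        bolus = np.where(
            t > 0, (t / tp) ** alpha * np.exp(alpha * (1.0 - t / tp)), 0.0
        )
    switch = 1.0 - np.exp(-((t / tp) ** 2))
    tail = sum(
        w * np.exp(-lam * t) for w, lam in zip(tail_fracs, tail_lambdas_per_s)
    )
    cp = amplitude_kBq_mL * (bolus + switch * tail)
    cp[0] = 0.0
    return InputFunction(t, cp)


def _tissue_curve(K1_per_min: float, k2_per_min: float, cp: InputFunction) -> np.ndarray:
    """Exact 1TC response for a piecewise-linear Cp on the fine grid.

    CT' = K1*Cp - k2*CT, integrated with the exponential-integrator
    recursion (exact for linear Cp within each step), evaluated via an IIR
    filter.
    """
    dt_min = cp.dt_s / 60.0
    k2 = float(k2_per_min)
    K1 = float(K1_per_min)
    c = cp.values
    a = math.exp(-k2 * dt_min)
    if k2 * dt_min > 1e-12:
        phi1 = (1.0 - a) / k2
        phi2 = (dt_min - phi1) / k2
    else:
        phi1 = dt_min
        phi2 = dt_min**2 / 2.0
    slope = np.diff(c) / dt_min
    b = K1 * (c[:-1] * phi1 + slope * phi2)
    x = np.concatenate(([0.0], b))
    return signal.lfilter([1.0], [1.0, -a], x)


def _frame_averages(
    values: np.ndarray, t_s: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    cumulative = np.concatenate(
        ([0.0], integrate.cumulative_trapezoid(values, t_s))
    )
    if schedule.ends_s[-1] > t_s[-1] + 1e-6:
        raise ValueError("schedule extends beyond the sampled time grid")
    lo = np.interp(schedule.starts_s, t_s, cumulative)
    hi = np.interp(schedule.ends_s, t_s, cumulative)
    return (hi - lo) / schedule.durations_s


def simulate_tac(
    p: KineticParams,
    cp: InputFunction,
    sched: FrameSchedule,
    region: str | None = None,
    subject: str | None = None,
) -> TimeActivityCurve:
    """Frame-duration-averaged one-tissue TAC (kBq/mL)."""
    min_dur = float(sched.durations_s.min())
    if cp.dt_s > min_dur / 5.0 + 1e-12:
        raise ValueError(
            f"Cp sampling ({cp.dt_s} s) must be at least 5x finer than the "
            f"shortest frame ({min_dur} s)"
        )
    ct = _tissue_curve(p.K1, p.k2_effective, cp)
    return TimeActivityCurve(
        sched, _frame_averages(ct, cp.t_s, sched), region=region, subject=subject
    )


def _peak_time_s(k2_per_min: float, cp: InputFunction) -> float:
    ct = _tissue_curve(1.0, k2_per_min, cp)
    return float(cp.t_s[int(np.argmax(ct))])


def _window_mean_fine(
    K1: float, k2: float, cp: InputFunction, t0_s: float, t1_s: float
) -> float:
    ct = _tissue_curve(K1, k2, cp)
    sel = (cp.t_s >= t0_s) & (cp.t_s <= t1_s)
    return float(np.trapezoid(ct[sel], cp.t_s[sel]) / (cp.t_s[sel][-1] - cp.t_s[sel][0]))


# ---------------------------------------------------------------------------
# Rendering


def _paint(
    labels: np.ndarray,
    values_by_label: Mapping[int, float],
    overrides: Sequence[tuple[np.ndarray, Mapping[int, float]]] = (),
) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    missing = [int(v) for v in present if int(v) not in values_by_label]
    if missing:
        raise ValueError(f"no value supplied for label(s) {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
    for lab, val in values_by_label.items():
        if lab <= lut.size - 1:
            lut[lab] = val
    out = lut[labels]
    for mask, table in overrides:
        lut_o = lut.copy()
        for lab, val in table.items():
            if lab <= lut_o.size - 1:
                lut_o[lab] = val
        out[mask] = lut_o[labels[mask]]
    return out


def _kernel_rms_factor(sigma_vox: np.ndarray) -> float:
    """SD attenuation of white noise under gaussian_filter with `sigma_vox`.

    Computed exactly from the discrete separable kernels (impulse response).
    """
    factor = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        radius = int(4.0 * float(s) + 0.5)
        delta = np.zeros(2 * radius + 1)
        delta[radius] = 1.0
        from scipy.ndimage import gaussian_filter1d

        k = gaussian_filter1d(delta, float(s))
        factor *= float(np.sqrt(np.sum(k * k)))
    return factor


_NOISE_FLOOR_KBQ_ML = 1e-3


def _render_volume(
    labels: np.ndarray,
    values_by_label: Mapping[int, float],
    voxel_size_mm: Sequence[float],
    psf_fwhm_mm: Sequence[float] | float,
    noise_scale: float,
    duration_s: float,
    rng: np.random.Generator,
    overrides: Sequence[tuple[np.ndarray, Mapping[int, float]]] = (),
    noise_correlation: str = "psf",
) -> np.ndarray:
    if noise_correlation not in ("psf", "white"):
        raise ValueError(f"unknown noise_correlation {noise_correlation!r}")
    painted = _paint(labels, values_by_label, overrides)
    blurred = gaussian_smooth(painted, psf_fwhm_mm, voxel_size_mm)
    if noise_scale <= 0:
        return blurred
    sd_map = noise_scale * np.sqrt(
        np.maximum(blurred, _NOISE_FLOOR_KBQ_ML) / duration_s
    )
    white = rng.standard_normal(labels.shape)
    sigma = fwhm_to_sigma(psf_fwhm_mm, voxel_size_mm)
    if noise_correlation == "psf" and np.any(sigma > 0):
        corr = gaussian_smooth(white, psf_fwhm_mm, voxel_size_mm)
        corr /= _kernel_rms_factor(sigma)
        return blurred + corr * sd_map
    return blurred + white * sd_map


def render_dynamic_image(
    labels: np.ndarray,
    tacs: Mapping[int, TimeActivityCurve],
    psf_fwhm_mm: Sequence[float] | float,
    noise_scale: float,
    seed: int | np.random.Generator,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    injected_dose_MBq: float = 185.1,
    body_weight_kg: float = 75.0,
    overrides: Sequence[tuple[np.ndarray, Mapping[int, TimeActivityCurve]]] = (),
    noise_correlation: str = "psf",
) -> DynamicImage:
    """Paint per-label TACs frame by frame, blur with the PSF, add
    duration-scaled noise. Reproducible for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedules = {id(t.schedule): t.schedule for t in tacs.values()}
    schedule = next(iter(tacs.values())).schedule
    for t in tacs.values():
        if len(t.schedule) != len(schedule) or not np.allclose(
            t.schedule.starts_s, schedule.starts_s
        ):
            raise ValueError("all TACs must share one frame schedule")
    n_frames = len(schedule)
    out = np.empty(tuple(labels.shape) + (n_frames,), dtype=np.float64)
    for i in range(n_frames):
        frame_vals = {lab: float(t.values[i]) for lab, t in tacs.items()}
        frame_overrides = [
            (mask, {lab: float(t.values[i]) for lab, t in table.items()})
            for mask, table in overrides
        ]
        out[..., i] = _render_volume(
            labels,
            frame_vals,
            voxel_size_mm,
            psf_fwhm_mm,
            noise_scale,
            float(schedule.durations_s[i]),
            rng,
            frame_overrides,
            noise_correlation,
        )
    return DynamicImage(
        out, schedule, tuple(voxel_size_mm), injected_dose_MBq, body_weight_kg
    )


def render_static(
    labels: np.ndarray,
    uptake: Mapping[int, float],
    psf_fwhm_mm: Sequence[float] | float,
    noise_scale: float,
    seed: int | np.random.Generator,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    duration_s: float = 1200.0,
    overrides: Sequence[tuple[np.ndarray, Mapping[int, float]]] = (),
    noise_correlation: str = "psf",
    dose_MBq: float | None = None,
    weight_kg: float | None = None,
) -> StaticImage:
    """Render a single 3D volume from per-label uptake values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vol = _render_volume(
        labels,
        uptake,
        voxel_size_mm,
        psf_fwhm_mm,
        noise_scale,
        duration_s,
        rng,
        overrides,
        noise_correlation,
    )
    return StaticImage(vol, tuple(voxel_size_mm), dose_MBq, weight_kg)


# ---------------------------------------------------------------------------
# Lesions


@dataclass(frozen=True)
class LesionSpec:
    """A unilateral lesion.

    severity_frac is the fractional reduction of the late-phase (30-60 min)
    signal in the core; perfusion_frac is the fractional reduction of K1
    over the broader perfusion/metabolic zone (radius
    `broad_radius_mm`, default twice the core radius), which is also the
    extent of the FDG lesion.
    """

    center_region: int
    side: str
    radius_mm: float
    severity_frac: float
    perfusion_frac: float = 0.0
    broad_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("lesion side must be 'left' or 'right'")
        if not 0.0 < self.severity_frac < 1.0:
            raise ValueError("severity_frac must lie in (0, 1)")
        if not 0.0 <= self.perfusion_frac < 1.0:
            raise ValueError("perfusion_frac must lie in [0, 1)")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def broad_radius(self) -> float:
        return self.broad_radius_mm if self.broad_radius_mm is not None else 2.0 * self.radius_mm


def lesion_geometry(
    labels: np.ndarray, spec: PhantomSpec, lesion: LesionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Core and broad lesion masks: spheres about the centroid of the
    center region, restricted to labeled voxels of the lesion hemisphere."""
    x, y, z = spec.coordinates_mm()
    center_mask = labels == lesion.center_region
    if not center_mask.any():
        raise ValueError(f"center region label {lesion.center_region} absent")
    cx = float(x[center_mask].mean())
    cy = float(y[center_mask].mean())
    cz = float(z[center_mask].mean())
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    hemi = x < 0 if lesion.side == "left" else x > 0
    base = (labels > 0) & hemi
    core = base & (d2 < lesion.radius_mm**2)
    broad = base & (d2 < lesion.broad_radius**2)
    return core, broad


def render_static_fdg(
    labels: np.ndarray,
    uptake: Mapping[int, float],
    lesion: LesionSpec | None,
    psf_fwhm_mm: Sequence[float] | float,
    noise_scale: float,
    seed: int | np.random.Generator,
    spec: PhantomSpec | None = None,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    duration_s: float = 1200.0,
    severity_frac: float | None = None,
    noise_correlation: str = "psf",
) -> StaticImage:
    """Static FDG-like volume; the lesion multiplies uptake by
    (1 - severity) over the broad lesion zone."""
    overrides: list[tuple[np.ndarray, Mapping[int, float]]] = []
    if lesion is not None:
        if spec is None:
            raise ValueError("spec is required to place a lesion")
        sev = lesion.severity_frac if severity_frac is None else severity_frac
        _, broad = lesion_geometry(labels, spec, lesion)
        overrides.append((broad, {lab: v * (1.0 - sev) for lab, v in uptake.items()}))
    return render_static(
        labels,
        uptake,
        psf_fwhm_mm,
        noise_scale,
        seed,
        voxel_size_mm,
        duration_s,
        overrides,
        noise_correlation,
    )


# ---------------------------------------------------------------------------
# Cohort generation


# baseline regional kinetics: name prefix -> (K1 mL/cm^3/min, VT, specific
# fraction, FDG uptake in SUV-like units). These absolute regional values
# are free parameters of the generator (only cortical peak statistics are
# externally constrained) and are documented as such.
_CORTEX_K1 = 0.25
_CORTEX_VT = 5.0
_CORTEX_FS = 0.90

_BASE_KINETICS: dict[str, tuple[float, float, float, float]] = {
    "temporal": (0.26, 5.2, 0.90, 8.5),
    "basal_ganglia": (0.28, 4.8, 0.88, 9.5),
    "thalamus": (0.27, 4.4, 0.85, 9.0),
    "centrum_semiovale": (0.12, 2.0, 0.10, 3.0),
    "cerebellum": (0.30, 4.6, 0.88, 7.5),
    "pons": (0.20, 3.5, 0.60, 5.0),
}


def _baseline_table(spec: PhantomSpec) -> dict[int, tuple[float, float, float, float]]:
    table: dict[int, tuple[float, float, float, float]] = {}
    for r in spec.regions:
        if r.kind == "cortex_sector":
            (i,) = r.params
            table[r.label] = (
                _CORTEX_K1,
                4.2 + 0.16 * i,
                0.84 + 0.012 * i,
                8.0 + 0.25 * i,
            )
        elif r.name == "blood_pool":
            continue  # vascular: carries the input function itself
        else:
            prefix = r.name.rsplit("_left", 1)[0].rsplit("_right", 1)[0]
            table[r.label] = _BASE_KINETICS[prefix]
    return table


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Cortical peak statistics and cohort sizes follow the emulated study
    (21 unblocked / 8 blocked; unblocked cortical peak SUV 7.4 +/- 1.6 at
    4.0 +/- 0.7 min, blocked 6.4 +/- 2.3 at 2.7 +/- 0.8 min; injected
    activities 185.1 +/- 13.6 MBq SV2A, 146.7 +/- 10.5 MBq FDG). The rest
    are generator choices documented in the methods note.
    """

    n_unblocked: int = 21
    n_blocked: int = 8
    frame_spec: str = "12x5,6x10,3x20,7x60,4x300,3x600"
    grid_shape: tuple[int, int, int] = (96, 96, 80)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    psf_fwhm_mm: tuple[float, float, float] = (6.6, 6.6, 5.1)
    noise_scale: float = 2.0
    fdg_noise_scale: float = 1.5
    dose_MBq: tuple[float, float] = (185.1, 13.6)
    fdg_dose_MBq: tuple[float, float] = (146.7, 10.5)
    weight_kg: tuple[float, float] = (75.0, 12.0)
    peak_suv_unblocked: tuple[float, float] = (7.4, 1.6)
    peak_time_min_unblocked: tuple[float, float] = (4.0, 0.7)
    peak_suv_blocked: tuple[float, float] = (6.4, 2.3)
    peak_time_min_blocked: tuple[float, float] = (2.7, 0.8)
    lesion_radius_mm: tuple[float, float] = (14.0, 3.0)
    broad_radius_mm: tuple[float, float] = (28.0, 5.0)
    lesion_severity: tuple[float, float] = (0.25, 0.05)
    lesion_perfusion: tuple[float, float] = (0.20, 0.04)
    fdg_lesion_severity: tuple[float, float] = (0.20, 0.04)
    lesion_shared_rho: float = 0.7
    broad_late_frac: float = 0.04
    lesion_sector: int = 3  # cortical sector index (0-based) hosting lesions
    p_left: float = 18.0 / 29.0
    perf_metab_sd: float = 0.10
    fdg_extra_sd: float = 0.06
    binding_sd: float = 0.12
    fdg_global_sd: float = 0.08
    input_dt_s: float = 0.5
    fdg_duration_s: float = 1200.0
    occupancy_max: float = 0.85

    def schedule(self) -> FrameSchedule:
        return parse_frame_spec(self.frame_spec)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in (
            "grid_shape",
            "voxel_size_mm",
            "psf_fwhm_mm",
            "dose_MBq",
            "fdg_dose_MBq",
            "weight_kg",
            "peak_suv_unblocked",
            "peak_time_min_unblocked",
            "peak_suv_blocked",
            "peak_time_min_blocked",
            "lesion_radius_mm",
            "broad_radius_mm",
            "lesion_severity",
            "lesion_perfusion",
            "fdg_lesion_severity",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Subject:
    """One synthetic subject: effective kinetics, lesion, and sampled
    regional measurements."""

    subject_id: str
    index: int
    blocked: bool
    occupancy: float
    washout_scale: float
    amplitude_scale: float
    dose_MBq: float
    weight_kg: float
    fdg_dose_MBq: float
    cp: InputFunction
    params: dict[int, KineticParams]
    lesion: LesionSpec
    fdg_severity_frac: float
    vt_scale_core: float
    vt_scale_broad: float
    fdg_uptake_suv: dict[int, float]
    tacs_true: dict[int, TimeActivityCurve] = field(repr=False, default_factory=dict)
    tacs_lesion_core: dict[int, TimeActivityCurve] = field(repr=False, default_factory=dict)
    tacs_lesion_broad: dict[int, TimeActivityCurve] = field(repr=False, default_factory=dict)
    truth: dict = field(default_factory=dict)

    def suv_factor(self) -> float:
        return 1.0 / (self.dose_MBq * 1000.0 / (self.weight_kg * 1000.0))


def _clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _solve_washout_scale(cp: InputFunction, target_peak_s: float) -> float:
    k2_base = _CORTEX_K1 / _CORTEX_VT
    lo, hi = 0.2, 12.0

    def f(s):
        return _peak_time_s(k2_base * s, cp) - target_peak_s

    if f(lo) <= 0:
        return lo
    if f(hi) >= 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-3))


def _solve_occupancy(
    cp: InputFunction, target_peak_s: float, washout_scale: float, occ_max: float
) -> float:
    k2_base = _CORTEX_K1 / _CORTEX_VT * washout_scale

    def peak(o):
        return _peak_time_s(k2_base / (1.0 - o * _CORTEX_FS), cp)

    if peak(0.0) <= target_peak_s:
        return 0.0
    if peak(occ_max) >= target_peak_s:
        return occ_max
    return float(
        optimize.brentq(lambda o: peak(o) - target_peak_s, 0.0, occ_max, xtol=1e-4)
    )


def _solve_vt_scale(
    cp: InputFunction,
    K1_lesion: float,
    k2_eff_normal: float,
    K1_normal: float,
    target_ratio: float,
    window: tuple[float, float] = (1800.0, 3600.0),
) -> float:
    """Distribution-volume scale giving the target late-window signal ratio."""
    ref = _window_mean_fine(K1_normal, k2_eff_normal, cp, *window)
    vt_normal = K1_normal / k2_eff_normal

    def ratio(v):
        return (
            _window_mean_fine(K1_lesion, K1_lesion / (vt_normal * v), cp, *window) / ref
        )

    lo, hi = 0.02, 2.0
    if ratio(hi) <= target_ratio:
        return hi
    if ratio(lo) >= target_ratio:
        return lo
    return float(
        optimize.brentq(lambda v: ratio(v) - target_ratio, lo, hi, xtol=1e-4)
    )


def _make_subject(
    index: int,
    blocked: bool,
    config: CohortConfig,
    seed: int,
    spec: PhantomSpec,
    schedule: FrameSchedule,
    base_table: Mapping[int, tuple[float, float, float, float]],
    blood_label: int,
) -> Subject:
    rng = np.random.default_rng([seed, index])
    dose = _clipped_normal(rng, *config.dose_MBq, 50.0, 500.0)
    weight = _clipped_normal(rng, *config.weight_kg, 35.0, 160.0)
    fdg_dose = _clipped_normal(rng, *config.fdg_dose_MBq, 50.0, 500.0)

    if blocked:
        peak_suv = _clipped_normal(rng, *config.peak_suv_blocked, 1.5, 15.0)
        peak_time = _clipped_normal(rng, *config.peak_time_min_blocked, 0.8, 10.0)
        # counterfactual unblocked washout: the subject's kinetics had they
        # not been treated, on top of which occupancy acts
        peak_time_unblocked = _clipped_normal(
            rng, *config.peak_time_min_unblocked, 0.8, 10.0
        )
    else:
        peak_suv = _clipped_normal(rng, *config.peak_suv_unblocked, 1.5, 15.0)
        peak_time = _clipped_normal(rng, *config.peak_time_min_unblocked, 0.8, 10.0)
        peak_time_unblocked = peak_time

    cp0 = parametric_input_function(
        duration_s=schedule.ends_s[-1] + 60.0, dt_s=config.input_dt_s
    )

    washout = _solve_washout_scale(cp0, peak_time_unblocked * 60.0)
    if blocked:
        occupancy = _solve_occupancy(
            cp0, min(peak_time, peak_time_unblocked) * 60.0, washout,
            config.occupancy_max,
        )
    else:
        occupancy = 0.0

    # amplitude: scale Cp so the representative cortical peak SUV matches
    k2_rep = _CORTEX_K1 / _CORTEX_VT * washout
    rep = _tissue_curve(
        _CORTEX_K1, k2_rep / (1.0 - occupancy * _CORTEX_FS), cp0
    )
    suv_per_kbq = weight * 1000.0 / (dose * 1000.0)
    amplitude = peak_suv / (float(rep.max()) * suv_per_kbq)
    cp = cp0.scaled(amplitude)

    fdg_global = (peak_suv / config.peak_suv_unblocked[0]) * math.exp(
        rng.normal(0.0, config.fdg_global_sd)
    )

    # biological jitter is drawn once per region *pair* and applied to both
    # hemispheres identically: outside the lesion the brain is symmetric
    def pair_key(label: int) -> str:
        name = spec.region_by_label[label].name
        for a, b in (("_left", ""), ("_right", ""), ("_L", "_"), ("_R", "_")):
            if a in name:
                return name.replace(a, b)
        return name

    jitter: dict[str, tuple[float, float, float]] = {}
    for key in sorted({pair_key(lab) for lab in base_table}):
        jitter[key] = (
            rng.normal(0.0, config.perf_metab_sd),
            rng.normal(0.0, config.binding_sd),
            rng.normal(0.0, config.fdg_extra_sd),
        )

    params: dict[int, KineticParams] = {}
    fdg_suv: dict[int, float] = {}
    for lab, (K1_r, VT_r, fs_r, fdg_r) in base_table.items():
        m, vb, fe = jitter[pair_key(lab)]
        K1 = K1_r * math.exp(m)
        VT = VT_r * math.exp(vb)
        params[lab] = KineticParams(
            K1=K1,
            k2=K1 / VT * washout,
            specific_fraction=fs_r,
            occupancy=occupancy,
        )
        fdg_suv[lab] = fdg_r * fdg_global * math.exp(m + fe)
    fdg_suv[blood_label] = 1.5 * fdg_global

    side = "left" if rng.random() < config.p_left else "right"
    sector_label = (101 if side == "left" else 201) + config.lesion_sector
    # lesion intensities share a latent per-subject factor (the paper-scale
    # cross-modality severity correlations), extents are drawn independently
    rho = config.lesion_shared_rho
    shared = rng.normal()

    def lesion_draw(mean, sd, lo, hi):
        z = rho * shared + math.sqrt(1.0 - rho**2) * rng.normal()
        return float(np.clip(mean + sd * z, lo, hi))

    severity = lesion_draw(*config.lesion_severity, 0.08, 0.60)
    perfusion = lesion_draw(*config.lesion_perfusion, 0.02, 0.40)
    fdg_sev = lesion_draw(*config.fdg_lesion_severity, 0.05, 0.50)
    radius = _clipped_normal(rng, *config.lesion_radius_mm, 8.0, 24.0)
    broad_radius = _clipped_normal(rng, *config.broad_radius_mm, 16.0, 42.0)
    broad_radius = max(broad_radius, radius + 4.0)
    lesion = LesionSpec(
        center_region=sector_label,
        side=side,
        radius_mm=radius,
        severity_frac=severity,
        perfusion_frac=perfusion,
        broad_radius_mm=broad_radius,
    )

    # calibrate the lesion distribution-volume scales against the center
    # region's own (jittered, possibly occupied) kinetics
    center_par = params[sector_label]
    K1_les = center_par.K1 * (1.0 - perfusion)
    vt_core = _solve_vt_scale(
        cp0, K1_les, center_par.k2_effective, center_par.K1, 1.0 - severity
    )
    vt_broad = _solve_vt_scale(
        cp0, K1_les, center_par.k2_effective, center_par.K1,
        1.0 - config.broad_late_frac,
    )

    subject = Subject(
        subject_id=f"sub-{index + 1:03d}",
        index=index,
        blocked=blocked,
        occupancy=occupancy,
        washout_scale=washout,
        amplitude_scale=amplitude,
        dose_MBq=dose,
        weight_kg=weight,
        fdg_dose_MBq=fdg_dose,
        cp=cp,
        params=params,
        lesion=lesion,
        fdg_severity_frac=fdg_sev,
        vt_scale_core=vt_core,
        vt_scale_broad=vt_broad,
        fdg_uptake_suv=fdg_suv,
    )

    sid = subject.subject_id
    for lab, p in params.items():
        name = spec.region_by_label[lab].name
        subject.tacs_true[lab] = simulate_tac(p, cp, schedule, region=name, subject=sid)
    subject.tacs_true[blood_label] = TimeActivityCurve(
        schedule, cp.frame_averages(schedule), region="blood_pool", subject=sid
    )
    for lab, p in params.items():
        name = spec.region_by_label[lab].name
        K1_l = p.K1 * (1.0 - perfusion)
        vt_eff = p.VT_effective
        for store, scale in (
            (subject.tacs_lesion_core, vt_core),
            (subject.tacs_lesion_broad, vt_broad),
        ):
            lesioned = KineticParams(
                K1=K1_l, k2=K1_l / (vt_eff * scale), specific_fraction=p.specific_fraction
            )
            store[lab] = simulate_tac(lesioned, cp, schedule, region=name, subject=sid)
    subject.tacs_lesion_core[blood_label] = subject.tacs_true[blood_label]
    subject.tacs_lesion_broad[blood_label] = subject.tacs_true[blood_label]

    subject.truth = {
        "subject": sid,
        "blocked": blocked,
        "occupancy": occupancy,
        "washout_scale": washout,
        "dose_MBq": dose,
        "weight_kg": weight,
        "fdg_dose_MBq": fdg_dose,
        "peak_suv_drawn": peak_suv,
        "peak_time_min_drawn": peak_time,
        "lesion_side": side,
        "lesion_center_label": sector_label,
        "lesion_radius_mm": lesion.radius_mm,
        "lesion_broad_radius_mm": lesion.broad_radius,
        "severity_frac": severity,
        "perfusion_frac": perfusion,
        "fdg_severity_frac": fdg_sev,
        "vt_scale_core": vt_core,
        "vt_scale_broad": vt_broad,
    }
    return subject


@dataclass
class Cohort:
    """A generated cohort: shared phantom, per-subject kinetics and
    sampled regional measurements, with on-demand image rendering."""

    config: CohortConfig
    seed: int
    phantom_spec: PhantomSpec
    schedule: FrameSchedule
    labels: np.ndarray
    subjects: list[Subject]
    truth: pd.DataFrame
    tac_table_suv: pd.DataFrame
    fdg_table_suv: pd.DataFrame

    @property
    def blocked_map(self) -> dict[str, bool]:
        return {s.subject_id: s.blocked for s in self.subjects}

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def lesion_masks(self, subject: Subject) -> tuple[np.ndarray, np.ndarray]:
        return lesion_geometry(self.labels, self.phantom_spec, subject.lesion)

    def _render_rng(self, subject: Subject, stream: str) -> np.random.Generator:
        streams = {"dynamic": 1, "fdg": 2, "window": 3}
        return np.random.default_rng([self.seed, subject.index, streams[stream]])

    def render_dynamic(self, subject: Subject, noise: bool = True) -> DynamicImage:
        core, broad = self.lesion_masks(subject)
        overrides = [
            (broad & ~core, subject.tacs_lesion_broad),
            (core, subject.tacs_lesion_core),
        ]
        return render_dynamic_image(
            self.labels,
            subject.tacs_true,
            self.config.psf_fwhm_mm,
            self.config.noise_scale if noise else 0.0,
            self._render_rng(subject, "dynamic"),
            self.config.voxel_size_mm,
            subject.dose_MBq,
            subject.weight_kg,
            overrides=overrides,
        )

    def render_window(
        self,
        subject: Subject,
        t0_s: float,
        t1_s: float,
        noise: bool = True,
    ) -> StaticImage:
        """Window-averaged SV2A volume rendered directly (noise scaled to
        the window duration)."""

        def wmean(tacs):
            out = {}
            idx = self.schedule.frames_within(t0_s, t1_s)
            if idx.size == 0:
                raise ValueError(f"no frame inside window [{t0_s}, {t1_s}]")
            w = self.schedule.durations_s[idx]
            for lab, tac in tacs.items():
                out[lab] = float(np.average(tac.values[idx], weights=w))
            return out

        core, broad = self.lesion_masks(subject)
        overrides = [
            (broad & ~core, wmean(subject.tacs_lesion_broad)),
            (core, wmean(subject.tacs_lesion_core)),
        ]
        return render_static(
            self.labels,
            wmean(subject.tacs_true),
            self.config.psf_fwhm_mm,
            self.config.noise_scale if noise else 0.0,
            self._render_rng(subject, "window"),
            self.config.voxel_size_mm,
            duration_s=t1_s - t0_s,
            overrides=overrides,
            dose_MBq=subject.dose_MBq,
            weight_kg=subject.weight_kg,
        )

    def render_fdg(self, subject: Subject, noise: bool = True) -> StaticImage:
        kbq_per_suv = subject.fdg_dose_MBq * 1000.0 / (subject.weight_kg * 1000.0)
        uptake = {lab: v * kbq_per_suv for lab, v in subject.fdg_uptake_suv.items()}
        img = render_static_fdg(
            self.labels,
            uptake,
            subject.lesion,
            self.config.psf_fwhm_mm,
            self.config.fdg_noise_scale if noise else 0.0,
            self._render_rng(subject, "fdg"),
            spec=self.phantom_spec,
            voxel_size_mm=self.config.voxel_size_mm,
            duration_s=self.config.fdg_duration_s,
            severity_frac=subject.fdg_severity_frac,
        )
        img.injected_dose_MBq = subject.fdg_dose_MBq
        img.body_weight_kg = subject.weight_kg
        return img

    def write(self, out_dir: str | Path, render: bool = True) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        p = out_dir / "atlas_labels.nii.gz"
        write_label_nifti(self.labels, self.config.voxel_size_mm, p)
        written.append(p)
        p = out_dir / "truth.csv"
        self.truth.to_csv(p, index=False)
        written.append(p)
        p = out_dir / "tacs_suv.csv"
        self.tac_table_suv.to_csv(p, index=False)
        written.append(p)
        p = out_dir / "fdg_suv.csv"
        self.fdg_table_suv.to_csv(p, index=False)
        written.append(p)
        if render:
            for s in self.subjects:
                dyn = self.render_dynamic(s)
                p = out_dir / f"{s.subject_id}_ucbh_dynamic.nii.gz"
                write_dynamic_nifti(dyn, p)
                written.append(p)
                fdg = self.render_fdg(s)
                p = out_dir / f"{s.subject_id}_fdg.nii.gz"
                write_static_nifti(fdg, p)
                written.append(p)
        return written


# regional sampling noise: a PSF-sized correlation cell covers roughly this
# many voxels on the default 2-mm grid, reducing the effective sample size
_REGION_NOISE_CELL_VOX = 30.0


def _sampled_tables(
    cohort_subjects: list[Subject],
    spec: PhantomSpec,
    labels: np.ndarray,
    schedule: FrameSchedule,
    config: CohortConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy SUV tables with region-level sampling noise.

    Regional noise mirrors image-space rendering: SD per frame is
    noise_scale*sqrt(C/duration) reduced by the effective number of
    independent resolution cells in the region.
    """
    counts = dict(zip(*np.unique(labels[labels > 0], return_counts=True)))
    name_of = {r.label: r.name for r in spec.regions}
    cortex = cortex_labels(spec)
    cortex_all = sorted(cortex["left"] | cortex["right"])

    tac_rows: list[dict] = []
    fdg_rows: list[dict] = []
    starts, durs = schedule.starts_s, schedule.durations_s
    for s in cohort_subjects:
        rng = np.random.default_rng([seed, s.index, 9])
        suv_f = s.suv_factor()
        values_by_label: dict[int, np.ndarray] = {}
        for lab, tac in s.tacs_true.items():
            n_eff = max(4.0, counts.get(lab, 4) / _REGION_NOISE_CELL_VOX)
            sd = (
                config.noise_scale
                * np.sqrt(np.maximum(tac.values, _NOISE_FLOOR_KBQ_ML) / durs)
                / np.sqrt(n_eff)
            )
            values_by_label[lab] = (tac.values + rng.normal(0.0, 1.0, sd.shape) * sd) * suv_f
        # composite cerebral cortex: voxel-count-weighted over the sectors
        w = np.array([counts.get(lab, 0) for lab in cortex_all], dtype=float)
        composite = np.average(
            np.stack([values_by_label[lab] for lab in cortex_all]), axis=0, weights=w
        )
        region_values = {name_of[lab]: v for lab, v in values_by_label.items()}
        region_values["cerebral_cortex"] = composite
        for region, vals in region_values.items():
            for i in range(len(schedule)):
                tac_rows.append(
                    {
                        "subject": s.subject_id,
                        "region": region,
                        "frame_index": i,
                        "start_s": float(starts[i]),
                        "duration_s": float(durs[i]),
                        "value": float(vals[i]),
                        "blocked": s.blocked,
                    }
                )
        fdg_by_label = {}
        for lab, v in s.fdg_uptake_suv.items():
            n_eff = max(4.0, counts.get(lab, 4) / _REGION_NOISE_CELL_VOX)
            sd = (
                config.fdg_noise_scale
                * np.sqrt(max(v, 1e-3) / config.fdg_duration_s)
                / np.sqrt(n_eff)
            )
            fdg_by_label[lab] = v + float(rng.normal(0.0, sd))
        fdg_regions = {name_of[lab]: v for lab, v in fdg_by_label.items()}
        fdg_regions["cerebral_cortex"] = float(
            np.average([fdg_by_label[lab] for lab in cortex_all], weights=w)
        )
        for region, v in fdg_regions.items():
            fdg_rows.append(
                {
                    "subject": s.subject_id,
                    "region": region,
                    "value": float(v),
                    "blocked": s.blocked,
                }
            )
    return pd.DataFrame(tac_rows), pd.DataFrame(fdg_rows)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    render: bool = False,
) -> Cohort:
    """Generate the paired synthetic cohort.

    Each subject has its own RNG stream derived from (seed, subject index),
    so truth tables are stable under cohort-size changes and two cohorts
    generated with the same seed are identical.
    """
    if config is None:
        config = CohortConfig()
    spec = default_phantom_spec(config.grid_shape, config.voxel_size_mm)
    schedule = config.schedule()
    labels = build_phantom(spec)
    base_table = _baseline_table(spec)
    blood_label = spec.label_by_name["blood_pool"]

    subjects: list[Subject] = []
    for i in range(config.n_unblocked + config.n_blocked):
        blocked = i >= config.n_unblocked
        subjects.append(
            _make_subject(
                i, blocked, config, seed, spec, schedule, base_table, blood_label
            )
        )

    # truth lesion volumes need the cortical masks
    cortex = cortex_labels(spec)
    voxel_mL = float(np.prod(config.voxel_size_mm)) / 1000.0
    for s in subjects:
        core, broad = lesion_geometry(labels, spec, s.lesion)
        in_cortex = np.isin(labels, sorted(cortex[s.lesion.side]))
        s.truth["core_volume_mL"] = float(np.count_nonzero(core & in_cortex)) * voxel_mL
        s.truth["broad_volume_mL"] = float(np.count_nonzero(broad & in_cortex)) * voxel_mL

    truth = pd.DataFrame([s.truth for s in subjects])
    tac_table, fdg_table = _sampled_tables(
        subjects, spec, labels, schedule, config, seed
    )
    cohort = Cohort(
        config=config,
        seed=seed,
        phantom_spec=spec,
        schedule=schedule,
        labels=labels,
        subjects=subjects,
        truth=truth,
        tac_table_suv=tac_table,
        fdg_table_suv=fdg_table,
    )
    if out_dir is not None:
        cohort.write(out_dir, render=render)
    return cohort
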