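"""Frame-schedule arithmetic, NIfTI I/O, SUV conversion, windowing and SUVR scaling.

Activity concentrations are carried in kBq/mL throughout; SUV uses the
g/mL convention (tissue density 1 g/mL), so ``SUV = C / (dose/weight)``
with the dose in kBq and the weight in grams.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "StaticImage",
    "ReferenceRegion",
    "parse_frame_spec",
    "suv",
    "window_average",
    "suvr",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "read_static_nifti",
    "write_static_nifti",
    "read_label_nifti",
    "write_label_nifti",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous dynamic-acquisition timeline.

    Parameters
    ----------
    frames
        Sequence of ``(start_s, duration_s)`` pairs. Starts must be strictly
        increasing and contiguous (each frame starts where the previous one
        ends); durations must be positive.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("schedule must contain at least one frame")
        for i, (start, dur) in enumerate(frames):
            if dur <= 0:
                raise ValueError(f"frame {i} has nonpositive duration {dur}")
            if i > 0:
                prev_start, prev_dur = frames[i - 1]
                if not np.isclose(start, prev_start + prev_dur):
                    raise ValueError(
                        f"frames not contiguous at index {i}: "
                        f"{prev_start + prev_dur} != {start}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    def frames_within(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Indices of frames fully contained in [t0_s, t1_s]."""
        eps = 1e-9
        return np.flatnonzero(
            (self.starts_s >= t0_s - eps) & (self.ends_s <= t1_s + eps)
        )


_FRAME_TOKEN = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+)\s*$")


def parse_frame_spec(spec: str, start_s: float = 0.0) -> FrameSchedule:
    """Expand a compact frame specification like ``"12x5,6x10,3x20"``.

    Each comma-separated token is ``count x duration_s``; the multiplication
    sign may be ``x`` or ``×``. The expanded schedule is contiguous and
    starts at `start_s`.
    """
    frames: list[tuple[float, float]] = []
    t = float(start_s)
    for token in str(spec).split(","):
        m = _FRAME_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed frame token {token!r}")
        count, dur = int(m.group(1)), float(m.group(2))
        if count < 1 or dur <= 0:
            raise ValueError(f"malformed frame token {token!r}")
        for _ in range(count):
            frames.append((t, dur))
            t += dur
    return FrameSchedule(tuple(frames))


@dataclass
class StaticImage:
    """A single 3D activity volume."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    injected_dose_MBq: float | None = None
    body_weight_kg: float | None = None
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"static image must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("static image contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class DynamicImage:
    """A 4D dynamic acquisition: frame axis last, schedule attached.

    voxels has shape ``(nx, ny, nz, n_frames)`` with axis 0 the left-right
    axis of the symmetric template grid.
    """

    voxels: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float]
    injected_dose_MBq: float
    body_weight_kg: float
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(f"dynamic image must be 4D, got shape {self.voxels.shape}")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame axis length {self.voxels.shape[3]} does not match "
                f"schedule length {len(self.schedule)}"
            )
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    def frame(self, i: int) -> StaticImage:
        return StaticImage(
            self.voxels[..., i],
            self.voxel_size_mm,
            self.injected_dose_MBq,
            self.body_weight_kg,
            units=self.units,
        )


@dataclass(frozen=True)
class ReferenceRegion:
    """A named reference region given as a set of atlas labels."""

    name: str
    labels: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(int(v) for v in self.labels))
        if not self.labels:
            raise ValueError(f"reference region {self.name!r} has an empty label set")


def suv(values: np.ndarray, dose_MBq: float, weight_kg: float) -> np.ndarray:
    """Convert activity concentration (kBq/mL) to SUV (g/mL convention)."""
    if dose_MBq <= 0:
        raise ValueError(f"injected dose must be positive, got {dose_MBq}")
    if weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {weight_kg}")
    dose_kBq = dose_MBq * 1000.0
    weight_g = weight_kg * 1000.0
    return np.asarray(values, dtype=np.float64) / (dose_kBq / weight_g)


def window_average(dyn: DynamicImage, t0_s: float, t1_s: float) -> StaticImage:
    """Duration-weighted mean over frames fully contained in [t0_s, t1_s]."""
    if t1_s <= t0_s:
        raise ValueError(f"empty window [{t0_s}, {t1_s}]")
    idx = dyn.schedule.frames_within(t0_s, t1_s)
    if idx.size == 0:
        raise ValueError(
            f"no frame fully contained in window [{t0_s}, {t1_s}] s"
        )
    durs = dyn.schedule.durations_s[idx]
    w = durs / durs.sum()
    voxels = np.tensordot(dyn.voxels[..., idx], w, axes=([3], [0]))
    return StaticImage(
        voxels,
        dyn.voxel_size_mm,
        dyn.injected_dose_MBq,
        dyn.body_weight_kg,
        units=dyn.units,
    )


def suvr(img: StaticImage, atlas: np.ndarray, ref: ReferenceRegion) -> StaticImage:
    """Voxelwise division by the mean over the reference-region labels."""
    atlas = np.asarray(atlas)
    if atlas.shape != img.voxels.shape:
        raise ValueError("atlas shape does not match image shape")
    mask = np.isin(atlas, list(ref.labels))
    if not mask.any():
        raise ValueError(f"reference region {ref.name!r} labels absent from atlas")
    ref_mean = float(img.voxels[mask].mean())
    if ref_mean <= 0:
        raise ValueError(
            f"reference region {ref.name!r} mean is nonpositive ({ref_mean})"
        )
    out = replace(img, voxels=img.voxels / ref_mean)
    out.units = f"SUVR({ref.name})"
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_static_nifti(img: StaticImage, path: str | Path) -> None:
    ni = nib.Nifti1Image(img.voxels.astype(np.float32), _affine(img.voxel_size_mm))
    ni.header.set_xyzt_units("mm")
    nib.save(ni, str(path))


def read_static_nifti(
    path: str | Path,
    dose_MBq: float | None = None,
    weight_kg: float | None = None,
) -> StaticImage:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    voxel_size = tuple(float(z) for z in ni.header.get_zooms()[:3])
    return StaticImage(data, voxel_size, dose_MBq, weight_kg)


def write_dynamic_nifti(dyn: DynamicImage, path: str | Path) -> None:
    ni = nib.Nifti1Image(dyn.voxels.astype(np.float32), _affine(dyn.voxel_size_mm))
    ni.header.set_xyzt_units("mm", "sec")
    nib.save(ni, str(path))


def read_dynamic_nifti(
    path: str | Path,
    schedule: FrameSchedule,
    dose_MBq: float,
    weight_kg: float,
) -> DynamicImage:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"{path}: frame axis length {data.shape[3]} does not match "
            f"declared schedule length {len(schedule)}"
        )
    voxel_size = tuple(float(z) for z in ni.header.get_zooms()[:3])
    return DynamicImage(data, schedule, voxel_size, dose_MBq, weight_kg)


def write_label_nifti(
    labels: np.ndarray, voxel_size_mm: Sequence[float], path: str | Path
) -> None:
    ni = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_size_mm))
    nib.save(ni, str(path))


def read_label_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: label volume is not integer-valued")
        data = rounded.astype(np.int32)
    voxel_size = tuple(float(z) for z in ni.header.get_zooms()[:3])
    return data.astype(np.int32), voxel_size
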