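"""Regional time-activity curves: extraction, peak characterization and
blocked-vs-unblocked group comparison per region and time window."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_core import DynamicImage, FrameSchedule, suv
from .stats_report import holm_sidak

__all__ = [
    "TimeActivityCurve",
    "extract_tac",
    "tac_peak",
    "window_mean",
    "compare_groups",
]


@dataclass
class TimeActivityCurve:
    """Per-frame mean activity for one region.

    values are in the units of the source image (kBq/mL or SUV); the time
    coordinate of each frame is its midpoint.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region: str | None = None
    subject: str | None = None
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size != len(self.schedule):
            raise ValueError(
                f"TAC length {self.values.size} does not match schedule "
                f"length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC contains non-finite values")

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.schedule.midpoints_s

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.schedule.midpoints_s / 60.0

    def to_suv(self, dose_MBq: float, weight_kg: float) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.schedule,
            suv(self.values, dose_MBq, weight_kg),
            region=self.region,
            subject=self.subject,
            units="SUV",
        )


def extract_tac(
    dyn: DynamicImage,
    mask: np.ndarray,
    region: str | None = None,
    subject: str | None = None,
) -> TimeActivityCurve:
    """Per-frame mean over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.voxels.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    if not mask.any():
        raise ValueError("empty mask")
    values = dyn.voxels[mask, :].mean(axis=0)
    return TimeActivityCurve(
        dyn.schedule, values, region=region, subject=subject, units=dyn.units
    )


def tac_peak(tac: TimeActivityCurve) -> tuple[float, float]:
    """Frame midpoint (minutes) and value of the TAC maximum; ties break to
    the earliest frame."""
    i = int(np.argmax(tac.values))
    return float(tac.midpoints_min[i]), float(tac.values[i])


def window_mean(tac: TimeActivityCurve, t0_s: float, t1_s: float) -> float:
    """Duration-weighted mean over frames fully contained in [t0_s, t1_s]."""
    idx = tac.schedule.frames_within(t0_s, t1_s)
    if idx.size == 0:
        raise ValueError(f"no frame fully contained in window [{t0_s}, {t1_s}] s")
    durs = tac.schedule.durations_s[idx]
    return float(np.average(tac.values[idx], weights=durs))


DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (0.0, 600.0),
    "late": (1800.0, 3600.0),
}


def compare_groups(
    tacs: pd.DataFrame,
    blocked: Mapping[str, bool] | None = None,
    windows: Mapping[str, tuple[float, float]] | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Blocked-vs-unblocked comparison of window-mean signal per region.

    Parameters
    ----------
    tacs
        Tidy table with columns ``subject, region, frame_index, start_s,
        duration_s, value`` and, if `blocked` is not given, a boolean
        ``blocked`` column.
    blocked
        Mapping subject -> blocked flag (overrides any column).
    windows
        Mapping window name -> (t0_s, t1_s); defaults to early 0-10 min and
        late 30-60 min.
    welch
        Use the unequal-variance t test (default); set False for the pooled
        variant.

    Returns one row per region x window with the group means, percent
    change, raw two-sided p and the Holm-Sidak adjusted p (adjusted across
    regions within each window).
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    df = tacs.copy()
    if blocked is not None:
        df["blocked"] = df["subject"].map(dict(blocked))
    if "blocked" not in df or df["blocked"].isna().any():
        raise ValueError("blocked status missing for some subjects")

    rows = []
    for win_name, (t0, t1) in windows.items():
        inside = (df["start_s"] >= t0 - 1e-9) & (
            df["start_s"] + df["duration_s"] <= t1 + 1e-9
        )
        w = df[inside]
        if w.empty:
            raise ValueError(f"window {win_name!r} contains no frames")
        means = (
            w.groupby(["region", "subject", "blocked"])
            .apply(
                lambda g: np.average(g["value"], weights=g["duration_s"]),
                include_groups=False,
            )
            .rename("mean")
            .reset_index()
        )
        for region, sub in means.groupby("region"):
            a = sub.loc[~sub["blocked"], "mean"].to_numpy(dtype=float)
            b = sub.loc[sub["blocked"], "mean"].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"region {region!r}: need >= 2 subjects per group"
                )
            if np.allclose(a, b.mean()) and np.allclose(b, b.mean()) and np.allclose(
                a.mean(), b.mean()
            ):
                p = 1.0
            else:
                p = float(
                    stats.ttest_ind(b, a, equal_var=not welch).pvalue
                )
            mean_u, mean_b = float(a.mean()), float(b.mean())
            rows.append(
                {
                    "region": region,
                    "window": win_name,
                    "mean_unblocked": mean_u,
                    "mean_blocked": mean_b,
                    "percent_change": 100.0 * (mean_b - mean_u) / mean_u,
                    "raw_p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = np.nan
    for win_name in windows:
        sel = out["window"] == win_name
        out.loc[sel, "adjusted_p"] = holm_sidak(
            out.loc[sel, "raw_p"].to_numpy()
        ).adjusted
    return out
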