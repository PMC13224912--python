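"""Framewise and windowed association between a dynamic tracer and a static
reference tracer, plus data-driven imaging-window selection.

The core quantity is the across-subject Pearson correlation between the
regional dynamic-tracer value in each frame and the regional static-tracer
uptake; runs of consecutively significant frames define the early/late
imaging windows.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_core import FrameSchedule

__all__ = [
    "pearson_r_p",
    "pearson_p_from_r",
    "framewise_correlation",
    "intrasubject_region_correlation",
    "select_windows",
]

logger = logging.getLogger(__name__)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n.

    Uses ``t = r*sqrt(n-2)/sqrt(1-r**2)`` on ``n-2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value.

    Raises on zero variance in either input (which is distinct from r = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in input vector")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    return r, pearson_p_from_r(r, n)


def framewise_correlation(
    tacs: pd.DataFrame,
    fdg: pd.DataFrame,
    region: str,
    scaling: str = "SUV",
) -> pd.DataFrame:
    """Per-frame Pearson correlation of a region's dynamic values with the
    static-tracer uptake across subjects.

    Parameters
    ----------
    tacs
        Tidy frame-level table with columns ``subject, region, frame_index,
        start_s, duration_s, value`` (values already on the desired scale,
        SUV or SUVR).
    fdg
        Table with columns ``subject, region, value`` for the static tracer.
    region
        Region to correlate.
    scaling
        Label recorded in the output (``"SUV"`` or ``"SUVR:<ref>"``).

    Returns a correlation-curve table with one row per frame:
    ``frame_index, midpoint_s, r, p, n, scaling``. Subjects missing either
    modality are excluded (the count is logged).
    """
    t = tacs[tacs["region"] == region]
    f = fdg[fdg["region"] == region].set_index("subject")["value"]
    if t.empty or f.empty:
        raise ValueError(f"region {region!r} absent from one of the inputs")
    dyn_subjects = set(t["subject"].unique())
    common = sorted(dyn_subjects & set(f.index))
    dropped = (dyn_subjects | set(f.index)) - set(common)
    if dropped:
        logger.info(
            "framewise_correlation: excluded %d subject(s) missing one "
            "modality", len(dropped)
        )
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 subjects with both modalities, got {len(common)}"
        )
    fdg_vec = f.loc[common].to_numpy(dtype=float)
    wide = (
        t[t["subject"].isin(common)]
        .pivot(index="subject", columns="frame_index", values="value")
        .loc[common]
    )
    meta = t.drop_duplicates("frame_index").set_index("frame_index")
    rows = []
    for frame_index in sorted(wide.columns):
        x = wide[frame_index].to_numpy(dtype=float)
        r, p = pearson_r_p(x, fdg_vec)
        start = float(meta.loc[frame_index, "start_s"])
        dur = float(meta.loc[frame_index, "duration_s"])
        rows.append(
            {
                "frame_index": int(frame_index),
                "start_s": start,
                "duration_s": dur,
                "midpoint_s": start + dur / 2.0,
                "r": r,
                "p": p,
                "n": len(common),
                "scaling": scaling,
            }
        )
    return pd.DataFrame(rows)


def intrasubject_region_correlation(
    dynamic_regional: Mapping[str, float],
    static_regional: Mapping[str, float],
    regions: Sequence[str],
) -> tuple[float, float]:
    """Within-subject correlation across atlas regions (one hemisphere)
    between a windowed dynamic image and the static tracer."""
    regions = list(regions)
    if len(regions) < 3:
        raise ValueError(f"need >= 3 regions, got {len(regions)}")
    missing = [r for r in regions if r not in dynamic_regional or r not in static_regional]
    if missing:
        raise ValueError(f"regions missing from inputs: {missing}")
    x = np.array([dynamic_regional[r] for r in regions], dtype=float)
    y = np.array([static_regional[r] for r in regions], dtype=float)
    return pearson_r_p(x, y)


def select_windows(
    curve: pd.DataFrame,
    alpha: float = 0.05,
    min_run: int = 3,
) -> list[tuple[float, float]]:
    """Maximal runs of >= `min_run` consecutive significant frames,
    reported as (start of first frame, end of last frame) in seconds.

    `curve` is a framewise-correlation table with columns ``frame_index,
    start_s, duration_s, p`` sorted by frame.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    c = curve.sort_values("frame_index").reset_index(drop=True)
    sig = (c["p"] < alpha).to_numpy()
    windows: list[tuple[float, float]] = []
    i = 0
    while i < len(sig):
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(sig) and sig[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            t0 = float(c.loc[i, "start_s"])
            t1 = float(c.loc[j, "start_s"] + c.loc[j, "duration_s"])
            windows.append((t0, t1))
        i = j + 1
    return windows
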