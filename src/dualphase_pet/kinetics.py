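"""Graphical kinetic outcome measures.

Logan plots estimate the total volume of distribution VT from an
image-derived input function (IDIF) and the distribution volume ratio DVR
from a reference-tissue Logan plot; VT ratios and DVR validate static
late-phase SUVR measures against dynamic modelling. All running integrals
use trapezoidal quadrature on frame midpoints (the input function on its
own fine grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .imaging_core import DynamicImage
from .tac_analysis import TimeActivityCurve, extract_tac

__all__ = [
    "LoganFit",
    "idif_extract",
    "logan_vt",
    "logan_dvr",
    "static_vs_kinetic_agreement",
]


@dataclass(frozen=True)
class LoganFit:
    """Result of a (reference) Logan graphical fit."""

    slope: float
    intercept: float
    r2: float
    t_star_min: float
    n_points: int


def idif_extract(
    dyn: DynamicImage,
    blood_mask: np.ndarray,
    dt_s: float = 0.5,
) -> "InputFunction":
    """Image-derived input function: the blood-pool TAC interpolated to a
    fine uniform grid (Cp forced to 0 at t = 0, clipped non-negative)."""
    from .phantom_sim import InputFunction

    tac = extract_tac(dyn, blood_mask, region="blood_pool")
    mid = tac.midpoints_s
    t = np.arange(0.0, float(dyn.schedule.ends_s[-1]) + dt_s / 2, dt_s)
    values = np.interp(t, np.concatenate(([0.0], mid)), np.concatenate(([0.0], tac.values)))
    values = np.clip(values, 0.0, None)
    values[0] = 0.0
    return InputFunction(t, values)


def _logan_xy(
    tac: TimeActivityCurve,
    input_integral_at_mid: np.ndarray,
    t_star_min: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mid_min = tac.midpoints_min
    ct = tac.values
    fit = mid_min >= t_star_min
    if fit.sum() < 3:
        raise ValueError(
            f"need >= 3 frames with midpoint >= t* = {t_star_min} min, "
            f"got {int(fit.sum())}"
        )
    if np.any(ct[fit] <= 0):
        raise ValueError("tissue activity must be positive in the fit range")
    ct_int = np.concatenate(
        ([0.0], integrate.cumulative_trapezoid(ct, mid_min))
    )
    x = input_integral_at_mid[fit] / ct[fit]
    y = ct_int[fit] / ct[fit]
    return x, y, fit


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def logan_vt(
    tac: TimeActivityCurve,
    input_fn: "InputFunction",
    t_star_min: float = 15.0,
) -> LoganFit:
    """Logan graphical VT: slope of int(CT)/CT vs int(Cp)/CT past t*.

    Times in minutes; the plasma integral is evaluated on the input
    function's fine grid and interpolated to frame midpoints.
    """
    cp_cum = np.concatenate(
        ([0.0], integrate.cumulative_trapezoid(input_fn.values, input_fn.t_s / 60.0))
    )
    cp_int_mid = np.interp(tac.midpoints_s, input_fn.t_s, cp_cum)
    x, y, fit = _logan_xy(tac, cp_int_mid, t_star_min)
    slope, intercept, r2 = _linear_fit(x, y)
    return LoganFit(slope, intercept, r2, t_star_min, int(fit.sum()))


def logan_dvr(
    tac_target: TimeActivityCurve,
    tac_reference: TimeActivityCurve,
    t_star_min: float = 15.0,
    k2_ref_per_min: float | None = None,
) -> LoganFit:
    """Reference-tissue Logan DVR: slope of int(CT)/CT vs
    (int(Cref) + Cref/k2_ref)/CT past t*.

    With `k2_ref_per_min` None the Cref/k2_ref correction is omitted
    (valid when the reference equilibrates quickly relative to t*).
    """
    if len(tac_target.schedule) != len(tac_reference.schedule):
        raise ValueError("target and reference TACs must share a schedule")
    mid_min = tac_reference.midpoints_min
    cref = tac_reference.values
    ref_int = np.concatenate(
        ([0.0], integrate.cumulative_trapezoid(cref, mid_min))
    )
    if k2_ref_per_min is not None:
        if k2_ref_per_min <= 0:
            raise ValueError("k2_ref must be positive")
        ref_int = ref_int + cref / k2_ref_per_min
    x, y, fit = _logan_xy(tac_target, ref_int, t_star_min)
    slope, intercept, r2 = _linear_fit(x, y)
    return LoganFit(slope, intercept, r2, t_star_min, int(fit.sum()))


def static_vs_kinetic_agreement(
    cohort,
    window_s: tuple[float, float] = (1800.0, 3600.0),
    reference: str = "centrum_semiovale",
    t_star_min: float = 15.0,
) -> pd.DataFrame:
    """Across-subject agreement of late-window SUVR with VT ratio and DVR.

    For every named region, correlates the window-mean SUVR (reference-
    region scaled) with the Logan VT ratio (subject's true input function)
    and with the reference Logan DVR across the cohort's subjects.
    Uses the noise-free regional TACs; k2_ref comes from generator truth.
    """
    from .crosstracer import pearson_r_p
    from .tac_analysis import window_mean

    spec = cohort.phantom_spec
    name_of = {r.label: r.name for r in spec.regions}
    ref_labels = sorted(
        lab for lab, name in name_of.items() if name.startswith(reference)
    )
    if not ref_labels:
        raise ValueError(f"no labels for reference {reference!r}")

    per_region: dict[str, dict[str, list[float]]] = {}
    for s in cohort.subjects:
        ref_tacs = [s.tacs_true[lab] for lab in ref_labels]
        ref_values = np.mean([t.values for t in ref_tacs], axis=0)
        ref_tac = TimeActivityCurve(cohort.schedule, ref_values, region=reference)
        ref_wmean = window_mean(ref_tac, *window_s)
        ref_fit = logan_vt(ref_tac, s.cp, t_star_min)
        k2_ref = float(
            np.mean([s.params[lab].k2_effective for lab in ref_labels])
        )
        for lab, tac in s.tacs_true.items():
            name = name_of.get(lab)
            if name is None or name == "blood_pool" or lab in ref_labels:
                continue
            suvr_val = window_mean(tac, *window_s) / ref_wmean
            vt = logan_vt(tac, s.cp, t_star_min)
            dvr = logan_dvr(tac, ref_tac, t_star_min, k2_ref)
            d = per_region.setdefault(
                name, {"suvr": [], "vtr": [], "dvr": []}
            )
            d["suvr"].append(suvr_val)
            d["vtr"].append(vt.slope / ref_fit.slope)
            d["dvr"].append(dvr.slope)

    rows = []
    for name, d in per_region.items():
        r_vtr, p_vtr = pearson_r_p(d["suvr"], d["vtr"])
        r_dvr, p_dvr = pearson_r_p(d["suvr"], d["dvr"])
        rows.append(
            {
                "region": name,
                "n": len(d["suvr"]),
                "r_suvr_vtr": r_vtr,
                "p_suvr_vtr": p_vtr,
                "r_suvr_dvr": r_dvr,
                "p_suvr_dvr": p_dvr,
            }
        )
    return pd.DataFrame(rows)
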