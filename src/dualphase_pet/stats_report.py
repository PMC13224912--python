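"""Shared statistical machinery and end-of-pipeline reporting.

Holm-Sidak step-down adjustment, one-way ANOVA with Tukey HSD pairwise
comparisons, and the cross-modality lesion comparison table (severity and
volume per modality, with pairwise Pearson correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdjustedPValues",
    "ModalityComparison",
    "holm_sidak",
    "anova_tukey",
    "modality_comparison_report",
]


@dataclass(frozen=True)
class AdjustedPValues:
    """Holm-Sidak adjusted p-values, in the original input order."""

    raw: np.ndarray
    adjusted: np.ndarray
    order: np.ndarray  # ascending sort permutation used for the step-down

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "adjusted", np.asarray(self.adjusted, dtype=float))
        object.__setattr__(self, "order", np.asarray(self.order, dtype=int))


def holm_sidak(raw_p: Sequence[float]) -> AdjustedPValues:
    """Holm-Sidak step-down multiplicity adjustment.

    Sort ascending; the i-th smallest (1-based) gets
    ``1 - (1 - p_(i))**(m - i + 1)``; a running maximum enforces step-down
    monotonicity; results are returned unsorted.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_p must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = m - np.arange(m)  # m, m-1, ..., 1
    adj_sorted = 1.0 - (1.0 - p[order]) ** exponents
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)
    adjusted = np.empty_like(adj_sorted)
    adjusted[order] = adj_sorted
    # 1-(1-p)^k >= p holds exactly; guard against float rounding below p
    adjusted = np.maximum(adjusted, p)
    return AdjustedPValues(raw=p, adjusted=adjusted, order=order)


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` has one row per
    unordered group pair with the Tukey-adjusted p-value (studentized
    range distribution).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels length must match number of groups")

    if all(np.allclose(g, arrays[0].mean()) for g in arrays) and all(
        np.allclose(g, g.mean()) for g in arrays
    ):
        # All observations identical: F = 0 by convention, nothing to detect.
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)

    with np.errstate(invalid="ignore", divide="ignore"):
        hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_a": float(arrays[i].mean()),
                    "mean_b": float(arrays[j].mean()),
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_tukey": float(hsd.pvalue[i, j]),
                }
            )
    return f_stat, p_val, pd.DataFrame(rows)


@dataclass
class ModalityComparison:
    """Cross-modality lesion comparison: severity and volume per modality."""

    severity: dict[str, np.ndarray]
    volume: dict[str, np.ndarray]
    severity_anova: tuple[float, float] | None = None
    volume_anova: tuple[float, float] | None = None
    severity_tukey: pd.DataFrame | None = None
    volume_tukey: pd.DataFrame | None = None
    severity_correlations: pd.DataFrame | None = None
    volume_correlations: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def _pairwise_correlations(values: Mapping[str, np.ndarray]) -> pd.DataFrame:
    from .crosstracer import pearson_r_p

    names = list(values)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = values[names[i]], values[names[j]]
            try:
                r, p = pearson_r_p(a, b)
                rows.append(
                    {"modality_a": names[i], "modality_b": names[j], "r": r,
                     "p": p, "n": len(a)}
                )
            except ValueError as exc:
                rows.append(
                    {"modality_a": names[i], "modality_b": names[j],
                     "r": np.nan, "p": np.nan, "n": len(a), "note": str(exc)}
                )
    return pd.DataFrame(rows)


def modality_comparison_report(
    severity: Mapping[str, Sequence[float]],
    volume: Mapping[str, Sequence[float]],
) -> ModalityComparison:
    """Assemble the per-modality lesion comparison.

    `severity` and `volume` map modality name (e.g. ``fdg``, ``early_ucbh``,
    ``late_ucbh``) to the paired per-subject values. Runs one-way ANOVA with
    Tukey pairwise tests on each metric and pairwise Pearson correlations
    between modalities. With a single subject per modality the tests are
    error-flagged in ``notes`` and only the means are reported.
    """
    sev = {k: np.asarray(v, dtype=float) for k, v in severity.items()}
    vol = {k: np.asarray(v, dtype=float) for k, v in volume.items()}
    lengths = {len(v) for v in sev.values()} | {len(v) for v in vol.values()}
    if len(lengths) != 1:
        raise ValueError("all modalities must have the same number of subjects")
    (n,) = lengths

    out = ModalityComparison(severity=sev, volume=vol)
    if n < 2:
        out.notes.append(
            "single subject: ANOVA, Tukey and correlations not computed"
        )
        return out
    names = list(sev)
    f, p, tk = anova_tukey([sev[k] for k in names], labels=names)
    out.severity_anova, out.severity_tukey = (f, p), tk
    f, p, tk = anova_tukey([vol[k] for k in names], labels=names)
    out.volume_anova, out.volume_tukey = (f, p), tk
    out.severity_correlations = _pairwise_correlations(sev)
    out.volume_correlations = _pairwise_correlations(vol)
    return out


def comparison_tables(comp: ModalityComparison) -> dict[str, pd.DataFrame]:
    """Render a ModalityComparison into flat tables (one per metric)."""
    tables: dict[str, pd.DataFrame] = {}
    for metric, values, anova, tukey, corr in (
        ("severity", comp.severity, comp.severity_anova, comp.severity_tukey,
         comp.severity_correlations),
        ("volume", comp.volume, comp.volume_anova, comp.volume_tukey,
         comp.volume_correlations),
    ):
        summary = pd.DataFrame(
            {
                "modality": list(values),
                "mean": [float(np.mean(v)) for v in values.values()],
                "sd": [float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
                       for v in values.values()],
                "n": [len(v) for v in values.values()],
            }
        )
        if anova is not None:
            summary["anova_F"] = anova[0]
            summary["anova_p"] = anova[1]
        tables[f"{metric}_summary"] = summary
        if tukey is not None:
            tables[f"{metric}_tukey"] = tukey
        if corr is not None:
            tables[f"{metric}_correlations"] = corr
    return tables
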