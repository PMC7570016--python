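"""Per-density hybrid summaries and density-response analysis.

The density response of a trait is summarized by its mean over all crosses,
locations and replicates at each density, and by the percent change of the
denser treatments relative to the thinnest planting:

    Change% = 100 * (mean_D - mean_D1) / mean_D1.

Hybrid-level summaries give the extreme crosses per density, comparisons
against a commercial check via LSD, and the per-cross optimum density
(the density maximizing grain yield per hectare).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trial import CrossMeanMatrix, TrialDesign, cross_id, cross_means

__all__ = [
    "DensityResponse",
    "change_percent",
    "density_means",
    "extremes",
    "compare_to_check",
    "optimum_density",
    "hybrid_summary",
]


def change_percent(mean_d: float, mean_d1: float) -> float:
    """100 * (mean_d - mean_d1) / mean_d1 relative to the baseline density."""
    if mean_d1 == 0:
        raise ValueError("baseline mean must be non-zero")
    return 100.0 * (mean_d - mean_d1) / mean_d1


@dataclass
class DensityResponse:
    """Per-density trait means and percent change from the baseline density."""

    trait: str
    means: pd.Series        # indexed by density label, in design order
    change_pct: pd.Series   # non-baseline densities only
    baseline: str


def density_means(obs, trait: str, densities=None, baseline: str | None = None) -> DensityResponse:
    """Mean over all crosses x locations x reps per density, plus Change%.

    ``densities`` fixes the level order (default: sorted labels);
    ``baseline`` defaults to the first level. Check entries are excluded.
    """
    df = obs[(obs["trait"] == trait) & (obs["parent2"] != "") & obs["parent2"].notna()]
    if df.empty:
        raise ValueError(f"no cross observations for trait {trait!r}")
    means = df.groupby("density")["value"].mean()
    order = list(densities) if densities is not None else sorted(means.index)
    means = means.reindex(order)
    if means.isna().any():
        raise ValueError(f"no data for density level(s) {list(means.index[means.isna()])}")
    base = baseline if baseline is not None else order[0]
    if base not in means.index:
        raise ValueError(f"baseline density {base!r} not present")
    ref = means[base]
    others = [d for d in order if d != base]
    change = pd.Series([change_percent(means[d], ref) for d in others], index=others)
    return DensityResponse(trait=trait, means=means, change_pct=change, baseline=base)


def extremes(m: CrossMeanMatrix) -> tuple[tuple[str, str], float, tuple[str, str], float]:
    """(min cross, min value, max cross, max value) with deterministic
    lexicographic tie-break on the sorted parent pair."""
    pairs = m.pair_series().sort_index()
    lo = pairs.min()
    hi = pairs.max()
    min_pair = sorted(pairs.index[pairs == lo])[0]
    max_pair = sorted(pairs.index[pairs == hi])[0]
    return tuple(min_pair), float(lo), tuple(max_pair), float(hi)


def compare_to_check(
    cross_mean: float, check_mean: float, lsd_05: float, lsd_01: float
) -> tuple[float, str]:
    """Classify the cross-vs-check difference as '' / '*' / '**' by LSD.

    Returns (signed difference, significance class); the sign says which
    way the cross deviates from the check.
    """
    if not (lsd_01 >= lsd_05 >= 0):
        raise ValueError("need lsd_01 >= lsd_05 >= 0")
    diff = cross_mean - check_mean
    if abs(diff) > lsd_01:
        return diff, "**"
    if abs(diff) > lsd_05:
        return diff, "*"
    return diff, ""


def optimum_density(gyph_means: Mapping[str, float]) -> str:
    """Density with the highest grain yield per hectare for one cross.

    ``gyph_means`` maps density label -> mean in the thin-to-dense order
    of its keys; exact ties resolve to the denser planting (equal yield at
    higher population is operationally preferable).
    """
    items = list(gyph_means.items())
    if len(items) < 2:
        raise ValueError("need at least two densities")
    best_label, best_val = items[0]
    for label, val in items[1:]:
        if val >= best_val:
            best_label, best_val = label, val
    return best_label


def hybrid_summary(obs, design: TrialDesign, trait: str) -> pd.DataFrame:
    """Table of min/max/mean cross performance per density (one row each),
    mirroring the standard multi-density trial summary."""
    rows = []
    for dens in design.densities:
        m = cross_means(obs, trait, design=design, density=dens)
        min_pair, lo, max_pair, hi = extremes(m)
        rows.append(
            {
                "trait": trait,
                "density": dens,
                "min_cross": "x".join(min_pair),
                "min": lo,
                "max_cross": "x".join(max_pair),
                "max": hi,
                "mean": float(m.pair_series().mean()),
            }
        )
    return pd.DataFrame(rows)
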