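"""Genetic-distance / hybrid-performance / SCA correlation analysis.

For each trait, three Pearson correlations are computed over the crosses
of the diallel: r(GD, F1) between parental genetic distance and mean F1
performance, r(GD, SCA) between distance and specific combining ability,
and r(F1, SCA). The F1 mean per cross is averaged across all environment
cells; SCA per cross is averaged over the per-density effect tables
(per-environment pooling is exposed through the ``sca_tables`` argument —
pass a single-table list for a single stratum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import stars
from .griffing import EffectTable
from .ssr import DistanceMatrix
from .trial import cross_id

__all__ = ["cross_gd", "pearson", "correlation_report", "CorrelationReport"]


def cross_gd(crosses: Sequence[tuple[str, str]], d: DistanceMatrix) -> pd.Series:
    """Parental genetic distance for each cross, looked up in ``d``."""
    vals, idx = [], []
    for p1, p2 in crosses:
        a, b = cross_id(p1, p2)  # rejects self-pairs
        if a not in d.labels or b not in d.labels:
            raise KeyError(f"parent {a!r} or {b!r} missing from distance matrix")
        vals.append(d.between(a, b))
        idx.append((a, b))
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["parent1", "parent2"]), name="gd")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationReport:
    """Per-trait r and p for (GD, F1), (GD, SCA) and (F1, SCA)."""

    table: pd.DataFrame  # index: trait; columns r_gd_f1, p_gd_f1, ..., n_pairs
    n_pairs: int

    def to_frame(self, alpha: float = 0.01) -> pd.DataFrame:
        """Presentation layout: one row per correlation, one column per
        trait, with '**' flags at ``alpha`` (the conventional report marks
        only the 1% level)."""
        out = {}
        for key in ("r_gd_f1", "r_gd_sca", "r_f1_sca"):
            pkey = key.replace("r_", "p_")
            out[key] = {
                t: f"{self.table.loc[t, key]:.2f}{'**' if self.table.loc[t, pkey] <= alpha else ''}"
                for t in self.table.index
            }
        return pd.DataFrame(out).T

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def correlation_report(
    d: DistanceMatrix,
    f1_means: pd.DataFrame,
    sca_tables: dict[str, Sequence[EffectTable]],
) -> CorrelationReport:
    """Correlate GD, F1 performance and SCA over the crosses, per trait.

    Parameters
    ----------
    d
        Parental genetic distance matrix.
    f1_means
        One column per trait, indexed by (parent1, parent2) cross pairs:
        the cross mean over all environment cells.
    sca_tables
        trait -> sequence of per-stratum effect tables whose SCA effects
        are averaged per cross (e.g. the three per-density tables).
    """
    traits = list(f1_means.columns)
    if set(traits) != set(sca_tables):
        raise ValueError("f1_means traits and sca_tables keys must match")
    crosses = list(f1_means.index)
    gd = cross_gd(crosses, d)

    rows = {}
    for trait in traits:
        tables = list(sca_tables[trait])
        sca_series = [t.sca_series() for t in tables]
        sca = pd.concat(sca_series, axis=1).mean(axis=1)
        if set(sca.index) != set(f1_means.index):
            raise ValueError(f"cross sets differ between f1_means and SCA for {trait!r}")
        sca = sca.reindex(f1_means.index)
        f1 = f1_means[trait].astype(float)
        r1, p1 = pearson(gd.to_numpy(), f1.to_numpy())
        r2, p2 = pearson(gd.to_numpy(), sca.to_numpy())
        r3, p3 = pearson(f1.to_numpy(), sca.to_numpy())
        rows[trait] = {
            "r_gd_f1": r1, "p_gd_f1": p1,
            "r_gd_sca": r2, "p_gd_sca": p2,
            "r_f1_sca": r3, "p_f1_sca": p3,
            "n_pairs": len(crosses),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "trait"
    return CorrelationReport(table=table, n_pairs=len(crosses))
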