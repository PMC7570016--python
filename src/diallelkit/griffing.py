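"""Griffing Method 4, Model I combining-ability analysis for half-diallels.

Method 4 analyses the crosses only (no parents, no reciprocals). For a set
of n parents with cross means y_ij the saturated fixed-effects model is

    y_ij = mu + g_i + g_j + s_ij,   sum_i g_i = 0,  sum_{j != i} s_ij = 0,

with closed-form estimators

    mu  = 2T / (n(n-1)),
    g_i = [n T_i - 2 T] / [n(n-2)],
    s_ij = y_ij - (T_i + T_j)/(n-2) + 2T/[(n-1)(n-2)],

where T_i = sum_{j != i} y_ij and T = sum_{i<j} y_ij. GCA effects capture
additive gene action (a parent's average contribution over its crosses);
SCA effects capture non-additive deviations specific to a cross.

The hybrids sum of squares partitions orthogonally into a GCA and an SCA
component; applied per environment cell and pooled, the same partition
splits each hybrids-by-environment interaction into GCA x E and SCA x E.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import stars
from .trial import CrossMeanMatrix, TrialDesign, cross_means

__all__ = [
    "gca_effects",
    "sca_effects",
    "cross_grand_mean",
    "partition_from_means",
    "partition_hybrid_ss",
    "gca_sca_ratio",
    "effect_standard_errors",
    "EffectSE",
    "SSPartition",
    "EffectTable",
    "effect_table",
]


def _totals(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Parent totals T_i and grand total T from a symmetric mean matrix."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    off = ~np.eye(n, dtype=bool)
    if not np.isfinite(v[off]).all():
        raise ValueError("cross-mean matrix has missing off-diagonal cells")
    t_i = np.where(off, v, 0.0).sum(axis=1)
    t = t_i.sum() / 2.0
    return t_i, t


def _check_n(n: int) -> None:
    if n < 3:
        raise ValueError("Griffing Method 4 requires at least 3 parents")


def cross_grand_mean(m: CrossMeanMatrix | np.ndarray) -> float:
    """Mean of all n(n-1)/2 cross means, mu = 2T/(n(n-1))."""
    values = m.values if isinstance(m, CrossMeanMatrix) else np.asarray(m)
    n = values.shape[0]
    _check_n(n)
    _, t = _totals(values)
    return 2.0 * t / (n * (n - 1))


def gca_effects(m: CrossMeanMatrix | np.ndarray) -> pd.Series:
    """General combining ability g_i = [n T_i - 2T] / [n(n-2)].

    Returns a Series indexed by parent code, summing to zero.
    """
    if isinstance(m, CrossMeanMatrix):
        values, parents = m.values, list(m.parents)
    else:
        values = np.asarray(m, dtype=float)
        parents = list(range(values.shape[0]))
    n = values.shape[0]
    _check_n(n)
    t_i, t = _totals(values)
    g = (n * t_i - 2.0 * t) / (n * (n - 2))
    return pd.Series(g, index=parents, name="gca")


def sca_effects(m: CrossMeanMatrix | np.ndarray) -> pd.DataFrame:
    """Specific combining ability s_ij as a symmetric DataFrame (NaN diagonal).

    s_ij = y_ij - (T_i + T_j)/(n-2) + 2T/[(n-1)(n-2)]; each row sums to
    zero over j != i, and mu + g_i + g_j + s_ij reconstructs y_ij exactly.
    """
    if isinstance(m, CrossMeanMatrix):
        values, parents = m.values, list(m.parents)
    else:
        values = np.asarray(m, dtype=float)
        parents = list(range(values.shape[0]))
    n = values.shape[0]
    _check_n(n)
    t_i, t = _totals(values)
    s = values - (t_i[:, None] + t_i[None, :]) / (n - 2) + 2.0 * t / ((n - 1) * (n - 2))
    np.fill_diagonal(s, np.nan)
    return pd.DataFrame(s, index=parents, columns=parents)


@dataclass
class SSPartition:
    """GCA/SCA split of the hybrids sum of squares (plot-observation basis)."""

    ss_gca: float
    ss_sca: float
    ss_hybrids: float
    df_gca: int
    df_sca: int
    r_basis: int

    @property
    def ms_gca(self) -> float:
        return self.ss_gca / self.df_gca

    @property
    def ms_sca(self) -> float:
        return self.ss_sca / self.df_sca


def partition_from_means(values: np.ndarray, r: int) -> SSPartition:
    """Partition the hybrids SS computed from a symmetric cross-mean matrix.

    ``r`` is the number of plot observations behind each cell mean; the SS
    are scaled to the plot basis (so they slot into the plot-level ANOVA).

        SS_GCA = r [ (1/(n-2)) sum T_i^2 - 4 T^2 / (n(n-2)) ]
        SS_SCA = SS_Hybrids - SS_GCA
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    _check_n(n)
    t_i, t = _totals(v)
    ss_gca = r * (np.sum(t_i**2) / (n - 2) - 4.0 * t**2 / (n * (n - 2)))
    iu = np.triu_indices(n, k=1)
    ybar = v[iu].mean()
    ss_hyb = r * float(np.sum((v[iu] - ybar) ** 2))
    ss_sca = ss_hyb - ss_gca
    # guard against tiny negative round-off
    if -1e-9 * max(1.0, ss_hyb) < ss_sca < 0:
        ss_sca = 0.0
    return SSPartition(
        ss_gca=float(ss_gca),
        ss_sca=float(ss_sca),
        ss_hybrids=ss_hyb,
        df_gca=n - 1,
        df_sca=n * (n - 3) // 2,
        r_basis=r,
    )


def partition_hybrid_ss(
    obs,
    design: TrialDesign,
    trait: str,
    density: str | None = None,
    location: str | None = None,
) -> SSPartition:
    """GCA/SCA partition of the hybrids SS for a stratum of a balanced trial."""
    m = cross_means(obs, trait, design=design, density=density, location=location)
    return partition_from_means(m.values, m.r_basis)


def gca_sca_ratio(ms_gca: float, ms_sca: float) -> float:
    """MS_GCA / MS_SCA; > 1 indicates predominantly additive gene action."""
    if ms_sca <= 0:
        raise ValueError("ms_sca must be positive")
    return ms_gca / ms_sca


def _pair_index(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def _gca_coefficients(n: int) -> np.ndarray:
    """Linear coefficients of g_i over the n(n-1)/2 cross means."""
    pairs = _pair_index(n)
    c = np.empty((n, len(pairs)))
    for i in range(n):
        for k, (a, b) in enumerate(pairs):
            c[i, k] = (n * (i in (a, b)) - 2.0) / (n * (n - 2))
    return c


def _sca_coefficients(n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Linear coefficients of s_ij over the cross means."""
    pairs = _pair_index(n)
    c = np.empty((len(pairs), len(pairs)))
    for r_, (i, j) in enumerate(pairs):
        for k, (a, b) in enumerate(pairs):
            c[r_, k] = (
                float((i, j) == (a, b))
                - ((i in (a, b)) + (j in (a, b))) / (n - 2)
                + 2.0 / ((n - 1) * (n - 2))
            )
    return c, pairs


@dataclass
class EffectSE:
    """Standard errors of combining-ability effects and their differences.

    Derived by exact propagation of Var(cell mean) = ms_error / r through
    the linear coefficients of each effect in the cross means — every
    effect is a fixed linear combination, so its variance is
    sum(coef^2) * ms_error / r.

    ``se_sca_diff`` is for two SCA effects sharing no parent;
    ``se_sca_diff_shared`` for two sharing one parent (NaN when the design
    is too small for the comparison to exist).
    """

    se_gca: float
    se_sca: float
    se_gca_diff: float
    se_sca_diff: float
    se_sca_diff_shared: float


def effect_standard_errors(n: int, ms_error: float, r: int) -> EffectSE:
    """SEs of g_i, s_ij and their pairwise differences for an n-parent diallel."""
    _check_n(n)
    if r < 1:
        raise ValueError("r must be >= 1")
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    var_mean = ms_error / r
    cg = _gca_coefficients(n)
    cs, pairs = _sca_coefficients(n)

    var_g = float(np.sum(cg[0] ** 2)) * var_mean
    var_g_diff = float(np.sum((cg[0] - cg[1]) ** 2)) * var_mean
    var_s = float(np.sum(cs[0] ** 2)) * var_mean

    lookup = {p: k for k, p in enumerate(pairs)}
    var_s_disjoint = np.nan
    if n >= 4:
        d = cs[lookup[(0, 1)]] - cs[lookup[(2, 3)]]
        var_s_disjoint = float(np.sum(d**2)) * var_mean
    d_shared = cs[lookup[(0, 1)]] - cs[lookup[(0, 2)]]
    var_s_shared = float(np.sum(d_shared**2)) * var_mean

    return EffectSE(
        se_gca=float(np.sqrt(var_g)),
        se_sca=float(np.sqrt(var_s)),
        se_gca_diff=float(np.sqrt(var_g_diff)),
        se_sca_diff=float(np.sqrt(var_s_disjoint)) if np.isfinite(var_s_disjoint) else np.nan,
        se_sca_diff_shared=float(np.sqrt(var_s_shared)),
    )


@dataclass
class EffectTable:
    """Combining-ability effects with SEs, significance and LSDs for a stratum."""

    stratum: str
    mu: float
    gca: pd.Series
    sca: pd.DataFrame
    se: EffectSE
    df_error: int
    lsd_gca: dict[float, float]
    lsd_sca: dict[float, float]
    gca_stars: pd.Series
    sca_stars: pd.DataFrame
    r_basis: int

    def gca_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gca": self.gca, "sig": self.gca_stars})

    def sca_series(self) -> pd.Series:
        parents = list(self.sca.index)
        idx, vals = [], []
        for i, j in itertools.combinations(range(len(parents)), 2):
            idx.append((parents[i], parents[j]))
            vals.append(self.sca.iloc[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["parent1", "parent2"]), name="sca")


def effect_table(
    obs,
    design: TrialDesign,
    trait: str,
    density: str | None = None,
    ms_error: float | None = None,
    df_error: int | None = None,
) -> EffectTable:
    """Estimate GCA/SCA effects for one trait stratum with tests and LSDs.

    Effects come from the cross means of the stratum (per density, averaged
    over locations and reps, in the standard presentation). Significance
    uses the sub-plot error of the combined split-plot ANOVA: pass
    ``ms_error``/``df_error`` to avoid recomputing it, otherwise the
    combined ANOVA is run on ``obs``.
    """
    m = cross_means(obs, trait, design=design, density=density)
    if ms_error is None or df_error is None:
        from .anova import combined_anova  # local import; anova fills GCA rows from here

        tab = combined_anova(obs, design, trait)
        row = tab.row("Error b")
        ms_error, df_error = row.MS, int(row.df)

    n = m.n
    mu = cross_grand_mean(m)
    g = gca_effects(m)
    s = sca_effects(m)
    se = effect_standard_errors(n, ms_error, m.r_basis)

    def star_of(value: float, se_val: float) -> str:
        if se_val == 0:
            return "" if value == 0 else "**"
        t = abs(value) / se_val
        p = 2 * stats.t.sf(t, df_error)
        return stars(p)

    g_stars = g.map(lambda v: star_of(v, se.se_gca))
    s_stars = s.map(lambda v: star_of(v, se.se_sca) if np.isfinite(v) else "")

    def lsd_of(se_diff: float, alpha: float) -> float:
        if not np.isfinite(se_diff):
            return np.nan
        return float(stats.t.ppf(1 - alpha / 2, df_error) * se_diff)

    return EffectTable(
        stratum=m.stratum,
        mu=mu,
        gca=g,
        sca=s,
        se=se,
        df_error=df_error,
        lsd_gca={0.05: lsd_of(se.se_gca_diff, 0.05), 0.01: lsd_of(se.se_gca_diff, 0.01)},
        lsd_sca={0.05: lsd_of(se.se_sca_diff, 0.05), 0.01: lsd_of(se.se_sca_diff, 0.01)},
        gca_stars=g_stars,
        sca_stars=s_stars,
        r_basis=m.r_basis,
    )
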