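"""Combined split-plot ANOVA across locations for half-diallel trials.

Densities sit on main plots within replicates, hybrids on sub-plots, so
there are two error strata: Error a (main-plot, = L x Rep x D residual)
tests densities and their location interaction; Error b (sub-plot) tests
every hybrid-containing source. Locations are treated as fixed and tested
against replicates-within-locations — a documented convention, since the
classical combined analysis admits either denominator.

All sums of squares use the closed forms for a balanced complete design
(sums of squared marginal means); unbalanced data are rejected outright.
The hybrids rows and each hybrids-by-environment interaction are further
partitioned into GCA and SCA components via the Griffing Method 4
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import stars
from .griffing import partition_from_means
from .trial import TrialDesign, validate_design

__all__ = [
    "AnovaTable",
    "combined_anova",
    "homogeneity_test",
    "error_b_by_location",
    "lsd",
    "SOURCE_ORDER",
]

SOURCE_ORDER = (
    "Locations (L)",
    "Rep(L)",
    "Densities (D)",
    "L x D",
    "Error a",
    "Hybrids (H)",
    "GCA",
    "SCA",
    "H x L",
    "GCA x L",
    "SCA x L",
    "H x D",
    "GCA x D",
    "SCA x D",
    "H x L x D",
    "GCA x L x D",
    "SCA x L x D",
    "Error b",
)

#: Sources that are sub-partitions of another row (excluded from the df total).
_DERIVED = frozenset(
    {"GCA", "SCA", "GCA x L", "SCA x L", "GCA x D", "SCA x D", "GCA x L x D", "SCA x L x D"}
)


@dataclass
class AnovaTable:
    """Sources / df / SS / MS / F / p table with denominator bookkeeping."""

    table: pd.DataFrame  # columns: source, df, SS, MS, F, p, sig, denominator
    trait: str
    gca_sca_ratio: float

    def row(self, source: str):
        match = self.table[self.table["source"] == source]
        if match.empty:
            raise KeyError(source)
        return next(match.itertuples(index=False))

    @property
    def total_df(self) -> int:
        keep = ~self.table["source"].isin(_DERIVED)
        return int(self.table.loc[keep, "df"].sum())

    @property
    def total_ss(self) -> float:
        keep = ~self.table["source"].isin(_DERIVED)
        return float(self.table.loc[keep, "SS"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _mean_sq_dev(marginal: np.ndarray, scale: float) -> float:
    """scale * sum((marginal - grand)^2) for a marginal-mean array."""
    return float(scale * np.sum((marginal - marginal.mean()) ** 2))


def combined_anova(obs, design: TrialDesign, trait: str) -> AnovaTable:
    """Combined split-plot ANOVA for one trait of a balanced complete trial.

    Observations are pivoted into a (location, rep, density, hybrid)
    array; each SS is a sum of squared marginal means times its replication
    factor, and Error b is the residual from the full interaction fit.
    Check entries are excluded — only the diallel crosses enter.
    """
    if isinstance(obs, pd.DataFrame):
        df = obs
    else:
        from .trial import observations_to_frame

        df = observations_to_frame(obs)
    df = df[(df["trait"] == trait) & (df["parent2"] != "") & df["parent2"].notna()].copy()
    if df.empty:
        raise ValueError(f"no cross observations for trait {trait!r}")

    report = validate_design(
        TrialDesign(
            parents=design.parents,
            crosses=design.crosses,
            locations=design.locations,
            densities=design.densities,
            reps=design.reps,
            plants_per_ha=design.plants_per_ha,
            check_entries=(),
        ),
        df,
    )
    if not report.balanced:
        raise ValueError(
            f"unbalanced data for trait {trait!r}: {len(report.missing)} missing, "
            f"{len(report.duplicated)} duplicated cells"
        )

    L, R, D = len(design.locations), design.reps, len(design.densities)
    hybrids = [f"{a}x{b}" for a, b in design.crosses]
    H = len(hybrids)
    n = design.n_parents

    li = {c: i for i, c in enumerate(design.locations)}
    ri = {r: r - 1 for r in range(1, R + 1)}
    di = {c: i for i, c in enumerate(design.densities)}
    hi = {c: i for i, c in enumerate(hybrids)}

    y = np.empty((L, R, D, H))
    entry = df["parent1"].str.cat(df["parent2"], sep="x")
    y[
        df["location"].map(li).to_numpy(),
        df["rep"].astype(int).map(ri).to_numpy(),
        df["density"].map(di).to_numpy(),
        entry.map(hi).to_numpy(),
    ] = df["value"].to_numpy()

    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    m_l = y.mean(axis=(1, 2, 3))
    m_lr = y.mean(axis=(2, 3))
    m_d = y.mean(axis=(0, 1, 3))
    m_ld = y.mean(axis=(1, 3))
    m_lrd = y.mean(axis=3)
    m_h = y.mean(axis=(0, 1, 2))
    m_lh = y.mean(axis=(1, 2))
    m_dh = y.mean(axis=(0, 1))
    m_ldh = y.mean(axis=1)

    ss = {}
    ss["Locations (L)"] = _mean_sq_dev(m_l, R * D * H)
    ss["Rep(L)"] = float(D * H * np.sum((m_lr - m_l[:, None]) ** 2))
    ss["Densities (D)"] = _mean_sq_dev(m_d, L * R * H)
    ss["L x D"] = float(R * H * np.sum((m_ld - m_l[:, None] - m_d[None, :] + grand) ** 2))
    ss["Error a"] = float(
        H * np.sum((m_lrd - m_lr[:, :, None] - m_ld[:, None, :] + m_l[:, None, None]) ** 2)
    )
    ss["Hybrids (H)"] = _mean_sq_dev(m_h, L * R * D)
    ss["H x L"] = float(R * D * np.sum((m_lh - m_l[:, None] - m_h[None, :] + grand) ** 2))
    ss["H x D"] = float(L * R * np.sum((m_dh - m_d[:, None] - m_h[None, :] + grand) ** 2))
    ss["H x L x D"] = float(
        R
        * np.sum(
            (
                m_ldh
                - m_lh[:, None, :]
                - m_dh[None, :, :]
                - m_ld[:, :, None]
                + m_l[:, None, None]
                + m_d[None, :, None]
                + m_h[None, None, :]
                - grand
            )
            ** 2
        )
    )
    fitted_sum = sum(
        ss[k]
        for k in (
            "Locations (L)", "Rep(L)", "Densities (D)", "L x D", "Error a",
            "Hybrids (H)", "H x L", "H x D", "H x L x D",
        )
    )
    ss["Error b"] = max(ss_total - fitted_sum, 0.0)

    dfs = {
        "Locations (L)": L - 1,
        "Rep(L)": L * (R - 1),
        "Densities (D)": D - 1,
        "L x D": (L - 1) * (D - 1),
        "Error a": L * (R - 1) * (D - 1),
        "Hybrids (H)": H - 1,
        "GCA": n - 1,
        "SCA": n * (n - 3) // 2,
        "H x L": (H - 1) * (L - 1),
        "GCA x L": (n - 1) * (L - 1),
        "SCA x L": (n * (n - 3) // 2) * (L - 1),
        "H x D": (H - 1) * (D - 1),
        "GCA x D": (n - 1) * (D - 1),
        "SCA x D": (n * (n - 3) // 2) * (D - 1),
        "H x L x D": (H - 1) * (L - 1) * (D - 1),
        "GCA x L x D": (n - 1) * (L - 1) * (D - 1),
        "SCA x L x D": (n * (n - 3) // 2) * (L - 1) * (D - 1),
        "Error b": L * D * (R - 1) * (H - 1),
    }

    # --- Griffing partition of hybrid rows -------------------------------
    def mean_matrix(vec_h: np.ndarray) -> np.ndarray:
        mat = np.full((n, n), np.nan)
        pos = {p: i for i, p in enumerate(design.parents)}
        for (a, b), v in zip(design.crosses, vec_h):
            mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = v
        return mat

    main = partition_from_means(mean_matrix(m_h), L * R * D)
    per_l = [partition_from_means(mean_matrix(m_lh[l]), R * D) for l in range(L)]
    per_d = [partition_from_means(mean_matrix(m_dh[d]), L * R) for d in range(D)]
    per_ld = [
        partition_from_means(mean_matrix(m_ldh[l, d]), R)
        for l in range(L)
        for d in range(D)
    ]

    def clip(x: float) -> float:
        return 0.0 if -1e-9 < x < 0 else x

    ss["GCA"] = main.ss_gca
    ss["SCA"] = main.ss_sca
    ss["GCA x L"] = clip(sum(p.ss_gca for p in per_l) - main.ss_gca)
    ss["SCA x L"] = clip(sum(p.ss_sca for p in per_l) - main.ss_sca)
    ss["GCA x D"] = clip(sum(p.ss_gca for p in per_d) - main.ss_gca)
    ss["SCA x D"] = clip(sum(p.ss_sca for p in per_d) - main.ss_sca)
    ss["GCA x L x D"] = clip(
        sum(p.ss_gca for p in per_ld) - ss["GCA x L"] - ss["GCA x D"] - main.ss_gca
    )
    ss["SCA x L x D"] = clip(
        sum(p.ss_sca for p in per_ld) - ss["SCA x L"] - ss["SCA x D"] - main.ss_sca
    )

    denominators = {
        "Locations (L)": "Rep(L)",
        "Densities (D)": "Error a",
        "L x D": "Error a",
        "Hybrids (H)": "Error b",
        "GCA": "Error b",
        "SCA": "Error b",
        "H x L": "Error b",
        "GCA x L": "Error b",
        "SCA x L": "Error b",
        "H x D": "Error b",
        "GCA x D": "Error b",
        "SCA x D": "Error b",
        "H x L x D": "Error b",
        "GCA x L x D": "Error b",
        "SCA x L x D": "Error b",
    }

    rows = []
    ms = {src: (ss[src] / dfs[src] if dfs[src] > 0 else np.nan) for src in SOURCE_ORDER}
    for src in SOURCE_ORDER:
        denom = denominators.get(src)
        if denom is not None and dfs[src] > 0 and dfs[denom] > 0 and ms[denom] > 0:
            f = ms[src] / ms[denom]
            p = float(stats.f.sf(f, dfs[src], dfs[denom]))
            sig = stars(p)
        else:
            f, p, sig = np.nan, np.nan, ""
        rows.append(
            {
                "source": src,
                "df": dfs[src],
                "SS": ss[src],
                "MS": ms[src],
                "F": f,
                "p": p,
                "sig": sig,
                "denominator": denom or "",
            }
        )
    table = pd.DataFrame(rows)
    ratio = ms["GCA"] / ms["SCA"] if ms["SCA"] > 0 else np.nan
    return AnovaTable(table=table, trait=trait, gca_sca_ratio=float(ratio))


def homogeneity_test(per_location_error_variances) -> tuple[float, float]:
    """Bartlett's test for homogeneity of error variances across locations.

    Input is a list of (variance, df) pairs — summary statistics, as kept
    from per-location analyses. Returns (chi-square statistic, p-value);
    combining locations is conventionally gated on p > alpha.
    """
    pairs = list(per_location_error_variances)
    if len(pairs) < 2:
        raise ValueError("need at least two variances")
    variances = np.array([v for v, _ in pairs], dtype=float)
    dof = np.array([d for _, d in pairs], dtype=float)
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    if np.any(dof < 1):
        raise ValueError("each variance needs df >= 1")
    k = len(pairs)
    df_tot = dof.sum()
    pooled = float(np.sum(dof * variances) / df_tot)
    statistic = df_tot * np.log(pooled) - float(np.sum(dof * np.log(variances)))
    c = 1.0 + (np.sum(1.0 / dof) - 1.0 / df_tot) / (3.0 * (k - 1))
    statistic = float(statistic / c)
    p = float(stats.chi2.sf(statistic, k - 1))
    return statistic, p


def error_b_by_location(obs, design: TrialDesign, trait: str) -> list[tuple[float, int]]:
    """Per-location sub-plot error variances (variance, df), for the
    homogeneity gate before combining locations."""
    out = []
    for loc in design.locations:
        sub_design = TrialDesign(
            parents=design.parents,
            crosses=design.crosses,
            locations=(loc,),
            densities=design.densities,
            reps=design.reps,
            plants_per_ha=design.plants_per_ha,
            check_entries=(),
        )
        df = obs[(obs["location"] == loc)]
        tab = combined_anova(df, sub_design, trait)
        row = tab.row("Error b")
        out.append((float(row.MS), int(row.df)))
    return out


def lsd(ms_error: float, df_error: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2 MS / n)."""
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if ms_error < 0 or n_per_mean < 1:
        raise ValueError("ms_error must be >= 0 and n_per_mean >= 1")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * np.sqrt(2.0 * ms_error / n_per_mean))
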