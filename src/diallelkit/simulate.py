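"""Synthetic half-diallel trials and SSR marker panels.

The trial generator is the generative twin of the combined split-plot
ANOVA model: for cross (i, j) grown in location l, replicate r, density d,

    y = mu + L_l + R(L)_lr + D_d + (LD)_ld + e_a(l, r, d)
        + g_i + g_j + s_ij + (hL)_hl + (hD)_hd + (hLD)_hld + e_b,

where e_a is the whole-plot (main-plot) error shared by every sub-plot of
a (location, replicate, density) main plot and e_b is the independent
sub-plot error. Random effects are drawn as independent normals and then
centered within their constraint groups, so the realized effects satisfy
the estimability constraints exactly — parameter-recovery tests can then
be exact rather than asymptotic.

All draws stem from a single integer seed through numpy's SeedSequence
stream splitting, so a configuration reproduces bit-identically.

The marker generator emulates a two-origin panel of homozygous inbred
lines: each group leans on its own anchor allele per locus, with the lean
controlled by ``divergence`` (0 = no group structure, 1 = fully private
anchor alleles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ssr import MarkerPanel
from .trial import COLUMNS, TrialDesign

__all__ = [
    "SimulationConfig",
    "MarkerSimConfig",
    "simulate_diallel_trial",
    "simulate_marker_panel",
    "make_standard_config",
    "make_marker_config",
]


def _center(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Remove the mean along each axis in turn (operators commute), so the
    result sums to zero over every listed axis at every level of the rest."""
    for ax in axes:
        x = x - x.mean(axis=ax, keepdims=True)
    return x


def _project_sca(a: np.ndarray) -> np.ndarray:
    """Project a symmetric zero-diagonal matrix onto the SCA constraint
    space (off-diagonal row sums all zero): subtract u_i + u_j with
    u_i = (T_i - U) / (n - 2), U = sum(T) / (2n - 2), T_i the row sums."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    t = a.sum(axis=1)
    u_tot = t.sum() / (2 * n - 2)
    u = (t - u_tot) / (n - 2)
    out = a - u[:, None] - u[None, :]
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class SimulationConfig:
    """Parameters of one simulated trait in a half-diallel split-plot trial.

    ``true_gca`` must sum to zero; ``true_sca`` must be symmetric with zero
    diagonal and zero row sums (over j != i). Environmental fixed effects
    are given per location / density / location x density cell and are
    expected centered (checked to 1e-8). Interaction terms with the listed
    SDs are drawn fresh per call (centered draws); ``sigma_a``/``sigma_b``
    are the whole-plot and sub-plot error SDs.
    """

    parents: tuple[str, ...]
    locations: tuple[str, ...]
    densities: tuple[str, ...]
    reps: int
    trait: str
    grand_mean: float
    true_gca: np.ndarray
    true_sca: np.ndarray
    loc_effects: np.ndarray
    density_effects: np.ndarray
    locdens_effects: np.ndarray
    sigma_rep: float = 0.0
    sd_hl: float = 0.0
    sd_hd: float = 0.0
    sd_hld: float = 0.0
    sigma_a: float = 0.0
    sigma_b: float = 0.0
    seed: int = 0
    plants_per_ha: dict[str, float] | None = None

    def __post_init__(self):
        self.true_gca = np.asarray(self.true_gca, dtype=float)
        self.true_sca = np.asarray(self.true_sca, dtype=float)
        self.loc_effects = np.asarray(self.loc_effects, dtype=float)
        self.density_effects = np.asarray(self.density_effects, dtype=float)
        self.locdens_effects = np.asarray(self.locdens_effects, dtype=float)
        n = len(self.parents)
        if n < 3:
            raise ValueError("need at least 3 parents")
        if self.true_gca.shape != (n,):
            raise ValueError("true_gca must have one entry per parent")
        if abs(self.true_gca.sum()) > 1e-12 * max(1.0, np.abs(self.true_gca).max()):
            raise ValueError("true_gca must sum to zero")
        if self.true_sca.shape != (n, n):
            raise ValueError("true_sca must be n x n")
        s = self.true_sca
        if not np.allclose(s, s.T):
            raise ValueError("true_sca must be symmetric")
        if not np.allclose(np.diag(s), 0.0):
            raise ValueError("true_sca diagonal must be zero")
        if not np.allclose(s.sum(axis=1), 0.0, atol=1e-10 * max(1.0, np.abs(s).max())):
            raise ValueError("true_sca rows must sum to zero")
        L, D = len(self.locations), len(self.densities)
        if self.loc_effects.shape != (L,) or self.density_effects.shape != (D,):
            raise ValueError("environment effect shapes do not match the design")
        if self.locdens_effects.shape != (L, D):
            raise ValueError("locdens_effects must be L x D")
        for name in ("sigma_rep", "sd_hl", "sd_hd", "sd_hld", "sigma_a", "sigma_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def design(self) -> TrialDesign:
        return TrialDesign.complete(
            self.parents, self.locations, self.densities, self.reps,
            plants_per_ha=self.plants_per_ha,
        )


def simulate_diallel_trial(config: SimulationConfig) -> pd.DataFrame:
    """Generate one trait's plot observations as a tidy DataFrame.

    The row order is deterministic: locations x reps x densities x crosses
    in design order. Identical configs (same seed) reproduce bit-identical
    tables.
    """
    design = config.design()
    L, R, D = len(config.locations), config.reps, len(config.densities)
    crosses = design.crosses
    H = len(crosses)
    n = len(config.parents)

    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_rep, rng_hl, rng_hd, rng_hld, rng_err = streams

    rep_eff = rng_rep.normal(0.0, config.sigma_rep, size=(L, R))
    if R > 1:
        rep_eff = _center(rep_eff, (1,))  # sum to zero within each location
    hl = _center(rng_hl.normal(0.0, config.sd_hl, size=(H, L)), (0, 1)) if config.sd_hl else np.zeros((H, L))
    hd = _center(rng_hd.normal(0.0, config.sd_hd, size=(H, D)), (0, 1)) if config.sd_hd else np.zeros((H, D))
    hld = (
        _center(rng_hld.normal(0.0, config.sd_hld, size=(H, L, D)), (0, 1, 2))
        if config.sd_hld
        else np.zeros((H, L, D))
    )
    e_a = rng_err.normal(0.0, config.sigma_a, size=(L, R, D))
    e_b = rng_err.normal(0.0, config.sigma_b, size=(L, R, D, H))

    pos = {p: i for i, p in enumerate(config.parents)}
    genet = np.array(
        [config.true_gca[pos[a]] + config.true_gca[pos[b]] + config.true_sca[pos[a], pos[b]] for a, b in crosses]
    )

    rows = []
    for l, loc in enumerate(config.locations):
        for r in range(R):
            for d, dens in enumerate(config.densities):
                base = (
                    config.grand_mean
                    + config.loc_effects[l]
                    + rep_eff[l, r]
                    + config.density_effects[d]
                    + config.locdens_effects[l, d]
                    + e_a[l, r, d]
                )
                vals = base + genet + hl[:, l] + hd[:, d] + hld[:, l, d] + e_b[l, r, d, :]
                for h, (a, b) in enumerate(crosses):
                    rows.append((loc, r + 1, dens, a, b, config.trait, vals[h]))
    return pd.DataFrame(rows, columns=list(COLUMNS))


def make_standard_config(seed: int = 0, trait: str = "GYPP") -> SimulationConfig:
    """Default conditions: an 8-parent, 28-cross diallel at 2 locations x
    3 densities x 3 replicates (504 plots per trait).

    Scales mimic a grain-yield-per-plant trait: grand mean near 150 g with
    density means stepping down roughly 170 / 154 / 135 g from thin to
    dense planting, and variance components back-solved approximately from
    the expected-mean-square identities of a combined split-plot analysis
    of such a trial. True GCA/SCA vectors are fixed draws (centered) from
    the seed, so every run states its own truth for recovery checks.
    """
    parents = tuple(f"L{i}" for i in range(1, 9))
    n = len(parents)
    ss = np.random.SeedSequence([seed, 0xD1A11E1])
    rng_g, rng_s = (np.random.default_rng(s) for s in ss.spawn(2))
    gca = rng_g.normal(0.0, 10.0, size=n)
    gca -= gca.mean()
    sca = rng_s.normal(0.0, 8.0, size=(n, n))
    sca = (sca + sca.T) / 2.0
    np.fill_diagonal(sca, 0.0)
    sca = _project_sca(sca)
    return SimulationConfig(
        parents=parents,
        locations=("LOC1", "LOC2"),
        densities=("D1", "D2", "D3"),
        reps=3,
        trait=trait,
        grand_mean=153.0,
        true_gca=gca,
        true_sca=sca,
        loc_effects=np.array([-4.9, 4.9]),
        density_effects=np.array([17.0, 1.0, -18.0]),
        locdens_effects=np.array([[1.5, -0.5, -1.0], [-1.5, 0.5, 1.0]]),
        sigma_rep=1.0,
        sd_hl=3.8,
        sd_hd=4.9,
        sd_hld=5.0,
        sigma_a=1.4,
        sigma_b=6.7,
        seed=seed,
        plants_per_ha={"D1": 59_500, "D2": 71_400, "D3": 83_300},
    )


@dataclass
class MarkerSimConfig:
    """Parameters of a simulated SSR panel of homozygous inbred lines."""

    lines: tuple[str, ...]
    group_assignment: dict[str, str]
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (2, 6)
    divergence: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if set(self.group_assignment) != set(self.lines):
            raise ValueError("group_assignment must cover exactly the lines")
        groups = set(self.group_assignment.values())
        for g in groups:
            if sum(v == g for v in self.group_assignment.values()) < 1:
                raise ValueError("empty group")
        lo, hi = self.alleles_per_locus
        if lo < 1 or hi < lo:
            raise ValueError("invalid alleles_per_locus range")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def simulate_marker_panel(config: MarkerSimConfig) -> MarkerPanel:
    """Draw one allele per line per locus (inbreds are homozygous).

    Per locus, k alleles are available; each group has an anchor allele
    (anchors distinct between groups when k >= #groups). A line carries
    its group anchor with probability ``divergence`` and otherwise a
    uniform random allele, so allele sharing is higher within groups than
    between whenever divergence > 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x55A]))
    groups = sorted(set(config.group_assignment.values()))
    lo, hi = config.alleles_per_locus
    loci = tuple(f"ssr{i + 1:02d}" for i in range(config.n_loci))
    alleles: dict[tuple[str, str], str] = {}
    for locus in loci:
        k = int(rng.integers(lo, hi + 1))
        allele_ids = [f"a{j + 1}" for j in range(k)]
        anchor_idx = rng.permutation(k)
        anchors = {g: allele_ids[anchor_idx[i % k]] for i, g in enumerate(groups)}
        for line in config.lines:
            if rng.random() < config.divergence:
                a = anchors[config.group_assignment[line]]
            else:
                a = allele_ids[int(rng.integers(k))]
            alleles[(line, locus)] = a
    return MarkerPanel(lines=tuple(config.lines), loci=loci, alleles=alleles)


def make_marker_config(seed: int = 0) -> MarkerSimConfig:
    """Default panel: 8 lines, first four local and last four exotic,
    10 polymorphic loci with 2-6 alleles, divergence 0.8."""
    lines = tuple(f"L{i}" for i in range(1, 9))
    assignment = {ln: ("local" if i < 4 else "exotic") for i, ln in enumerate(lines)}
    return MarkerSimConfig(lines=lines, group_assignment=assignment, seed=seed)
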