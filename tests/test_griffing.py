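"""Griffing Method 4 estimators against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from diallelkit import griffing
from diallelkit.griffing import (
    cross_grand_mean,
    effect_standard_errors,
    gca_effects,
    gca_sca_ratio,
    partition_from_means,
    partition_hybrid_ss,
    sca_effects,
)
from diallelkit.datasets import REFERENCE_COMBINING_MEAN_SQUARES, REFERENCE_GCA_SCA_RATIOS
from diallelkit._utils import round_half_up


def random_mean_matrix(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(20, 5, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, np.nan)
    return v


def constrained_ls_oracle(values):
    """Solve y_ij = mu + g_i + g_j + s_ij with sum g = 0 and per-parent
    zero SCA row sums as one stacked linear system (the model is
    saturated, so the solution interpolates the data exactly)."""
    n = values.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    npar = 1 + n + len(pairs)
    rows, rhs = [], []
    for k, (i, j) in enumerate(pairs):
        row = np.zeros(npar)
        row[0] = 1.0
        row[1 + i] = 1.0
        row[1 + j] = 1.0
        row[1 + n + k] = 1.0
        rows.append(row)
        rhs.append(values[i, j])
    row = np.zeros(npar)
    row[1 : 1 + n] = 1.0
    rows.append(row)
    rhs.append(0.0)
    for i in range(n):
        row = np.zeros(npar)
        for k, (a, b) in enumerate(pairs):
            if i in (a, b):
                row[1 + n + k] = 1.0
        rows.append(row)
        rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    mu = sol[0]
    g = sol[1 : 1 + n]
    s = np.full((n, n), np.nan)
    for k, (i, j) in enumerate(pairs):
        s[i, j] = s[j, i] = sol[1 + n + k]
    return mu, g, s


def test_gca_closed_form_toy():
    """n=4 worked example: g = (-4.5, -0.5, 1.5, 3.5)."""
    v = np.full((4, 4), np.nan)
    for (i, j), y in zip(itertools.combinations(range(4), 2), [10, 12, 14, 16, 18, 20]):
        v[i, j] = v[j, i] = y
    np.testing.assert_allclose(gca_effects(v).to_numpy(), [-4.5, -0.5, 1.5, 3.5])
    # additive table -> all SCA zero
    s = sca_effects(v).to_numpy()
    assert np.nanmax(np.abs(s)) < 1e-12


def test_sca_perturbation_toy():
    """Raising one cell by 4 spreads as +4/3 there, -2/3 in same-row cells."""
    a = np.array([3.0, 7.0, 9.0, 11.0])
    v = a[:, None] + a[None, :]
    np.fill_diagonal(v, np.nan)
    v[0, 1] = v[1, 0] = v[0, 1] + 4.0
    s = sca_effects(v)
    assert s.iloc[0, 1] == pytest.approx(4 / 3)
    assert s.iloc[0, 2] == pytest.approx(-2 / 3)
    assert s.iloc[0, 3] == pytest.approx(-2 / 3)
    rowsums = np.nansum(s.to_numpy(), axis=1)
    np.testing.assert_allclose(rowsums, 0.0, atol=1e-12)


@pytest.mark.parametrize("n", range(3, 9))
def test_effects_equal_constrained_least_squares(n):
    """Closed forms coincide with the constrained LS fit for n=3..8."""
    v = random_mean_matrix(n, seed=100 + n)
    mu_o, g_o, s_o = constrained_ls_oracle(v)
    assert cross_grand_mean(v) == pytest.approx(mu_o, abs=1e-9)
    np.testing.assert_allclose(gca_effects(v).to_numpy(), g_o, atol=1e-9)
    s = sca_effects(v).to_numpy()
    iu = np.triu_indices(n, 1)
    np.testing.assert_allclose(s[iu], s_o[iu], atol=1e-9)


@pytest.mark.parametrize("n", [4, 6, 8])
def test_zero_sum_and_reconstruction(n):
    v = random_mean_matrix(n, seed=7 * n)
    g = gca_effects(v).to_numpy()
    s = sca_effects(v).to_numpy()
    mu = cross_grand_mean(v)
    assert abs(g.sum()) < 1e-10
    np.testing.assert_allclose(np.nansum(s, axis=1), 0.0, atol=1e-10)
    for i, j in itertools.combinations(range(n), 2):
        assert mu + g[i] + g[j] + s[i, j] == pytest.approx(v[i, j], abs=1e-10)


def test_translation_invariance():
    v = random_mean_matrix(5, seed=3)
    g1 = gca_effects(v).to_numpy()
    g2 = gca_effects(v + 17.5).to_numpy()
    np.testing.assert_allclose(g1, g2, atol=1e-10)


def test_small_n_rejected():
    v = random_mean_matrix(2, seed=0)
    with pytest.raises(ValueError):
        gca_effects(np.array([[np.nan, 1.0], [1.0, np.nan]]))


def test_partition_additivity_and_oracle():
    """SS_GCA + SS_SCA equals the hybrids SS about the cross grand mean."""
    v = random_mean_matrix(4, seed=12)
    part = partition_from_means(v, r=1)
    iu = np.triu_indices(4, 1)
    ss_h = np.sum((v[iu] - v[iu].mean()) ** 2)
    assert part.ss_gca + part.ss_sca == pytest.approx(ss_h, rel=1e-10)
    assert part.df_gca == 3 and part.df_sca == 2
    # direct SS oracle: (n-2) * sum g_i^2 on the mean basis
    g = gca_effects(v).to_numpy()
    assert part.ss_gca == pytest.approx(2 * np.sum(g**2), rel=1e-10)


def test_partition_pure_gca_simulation(noiseless_trial, noiseless_config):
    import dataclasses

    cfg = dataclasses.replace(noiseless_config, true_sca=np.zeros((8, 8)), sd_hl=0.0)
    from diallelkit.simulate import simulate_diallel_trial

    obs = simulate_diallel_trial(cfg)
    part = partition_hybrid_ss(obs, cfg.design(), "GYPP")
    assert part.ss_sca == pytest.approx(0.0, abs=1e-7)
    assert part.df_sca == 8 * 5 // 2 == 20


def test_gca_sca_ratio_printed_values():
    """MS ratios reproduce the published 2-dp table across all traits."""
    for trait, (ms_g, ms_s) in REFERENCE_COMBINING_MEAN_SQUARES.items():
        assert round_half_up(gca_sca_ratio(ms_g, ms_s)) == pytest.approx(
            REFERENCE_GCA_SCA_RATIOS[trait], abs=0.0101  # one unit in the last printed digit
        )
    assert gca_sca_ratio(5.0, 5.0) == 1.0
    with pytest.raises(ValueError):
        gca_sca_ratio(1.0, 0.0)


def test_effect_se_monte_carlo_oracle():
    """Coefficient-propagation SEs match the Monte-Carlo SD of estimated
    effects over 10,000 noise draws within 2%."""
    n, ms_error, r = 8, 45.0, 6
    se = effect_standard_errors(n, ms_error, r)
    rng = np.random.default_rng(2024)
    pairs = list(itertools.combinations(range(n), 2))
    draws = rng.normal(0.0, np.sqrt(ms_error / r), size=(10_000, len(pairs)))
    g_hat = np.empty((10_000, n))
    s_hat01 = np.empty(10_000)
    for t, noise in enumerate(draws):
        v = np.full((n, n), np.nan)
        for k, (i, j) in enumerate(pairs):
            v[i, j] = v[j, i] = noise[k]
        g_hat[t] = gca_effects(v).to_numpy()
        s_hat01[t] = sca_effects(v).iloc[0, 1]
    assert np.std(g_hat[:, 0]) == pytest.approx(se.se_gca, rel=0.02)
    assert np.std(s_hat01) == pytest.approx(se.se_sca, rel=0.02)
    assert np.std(g_hat[:, 0] - g_hat[:, 1]) == pytest.approx(se.se_gca_diff, rel=0.02)


def test_effect_se_scaling_and_degenerate():
    se1 = effect_standard_errors(8, 2.0, 1)
    se4 = effect_standard_errors(8, 2.0, 4)
    assert se4.se_gca == pytest.approx(se1.se_gca / 2)
    se0 = effect_standard_errors(8, 0.0, 6)
    assert se0.se_gca == se0.se_sca == 0.0
    with pytest.raises(ValueError):
        effect_standard_errors(8, 1.0, 0)


def test_effect_table_stars_and_lsd(standard_trial):
    design, obs = standard_trial
    et = griffing.effect_table(obs, design, "GYPP", density="D1")
    assert abs(et.gca.sum()) < 1e-9
    assert et.r_basis == 6
    assert et.lsd_gca[0.01] > et.lsd_gca[0.05] > 0
    # reconstruction identity on the stratum means
    from diallelkit.trial import cross_means

    m = cross_means(obs, "GYPP", design=design, density="D1")
    for a, b in design.crosses:
        assert et.mu + et.gca[a] + et.gca[b] + et.sca.loc[a, b] == pytest.approx(
            m.y(a, b), abs=1e-10
        )
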