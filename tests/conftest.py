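import numpy as np
import pytest
from dataclasses import replace

from diallelkit import simulate, trial


@pytest.fixture(scope="session")
def standard_config():
    return simulate.make_standard_config(seed=11)


@pytest.fixture(scope="session")
def standard_trial(standard_config):
    obs = simulate.simulate_diallel_trial(standard_config)
    return standard_config.design(), obs


@pytest.fixture(scope="session")
def noiseless_config(standard_config):
    return replace(
        standard_config,
        sigma_a=0.0, sigma_b=0.0, sigma_rep=0.0,
        sd_hl=0.0, sd_hd=0.0, sd_hld=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_config):
    obs = simulate.simulate_diallel_trial(noiseless_config)
    return noiseless_config.design(), obs


@pytest.fixture(scope="session")
def null_hybrid_f_stats():
    """F(Hybrids) statistics from 1000 pure-null simulations (g = s = 0,
    no hybrid-by-environment interactions) at the standard trial size."""
    from diallelkit.anova import combined_anova

    base = simulate.make_standard_config(seed=501)
    null = replace(
        base,
        true_gca=np.zeros(8), true_sca=np.zeros((8, 8)),
        sd_hl=0.0, sd_hd=0.0, sd_hld=0.0,
        sigma_a=1.0, sigma_b=1.0,
    )
    design = null.design()
    fs = np.empty(1000)
    for k in range(1000):
        obs = simulate.simulate_diallel_trial(replace(null, seed=20_000 + k))
        fs[k] = combined_anova(obs, design, "GYPP").row("Hybrids (H)").F
    return fs


def small_config(seed=0, n=4, L=2, D=2, reps=2, **overrides):
    """Compact trial for brute-force oracle comparisons."""
    parents = tuple(f"P{i}" for i in range(1, n + 1))
    rng = np.random.default_rng(seed + 1000)
    gca = rng.normal(0, 3, n)
    gca -= gca.mean()
    sca = rng.normal(0, 2, (n, n))
    sca = (sca + sca.T) / 2
    np.fill_diagonal(sca, 0.0)
    sca = simulate._project_sca(sca)
    loc = rng.normal(0, 2, L)
    loc -= loc.mean()
    dens = rng.normal(0, 2, D)
    dens -= dens.mean()
    ld = rng.normal(0, 1, (L, D))
    ld = ld - ld.mean(axis=0) - ld.mean(axis=1, keepdims=True) + ld.mean()
    params = dict(
        parents=parents,
        locations=tuple(f"S{i}" for i in range(1, L + 1)),
        densities=tuple(f"D{i}" for i in range(1, D + 1)),
        reps=reps,
        trait="GYPP",
        grand_mean=50.0,
        true_gca=gca,
        true_sca=sca,
        loc_effects=loc,
        density_effects=dens,
        locdens_effects=ld,
        sigma_rep=0.5,
        sd_hl=1.0,
        sd_hd=1.0,
        sd_hld=1.0,
        sigma_a=0.7,
        sigma_b=1.3,
        seed=seed,
    )
    params.update(overrides)
    return simulate.SimulationConfig(**params)
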