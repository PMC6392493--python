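import numpy as np
import pytest

import traitgrowth as tg

# Sampler profiles for tests: enough iterations to get usable posteriors on
# the tiny fixtures without dominating suite runtime.
FAST = tg.SamplerSettings(chains=1, warmup=150, draws=150, seed=0, leapfrog_steps=32)
TINY = tg.SamplerSettings(chains=1, warmup=60, draws=40, seed=0, leapfrog_steps=16)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_dataset():
    """4 species, Monod curves, informative traits, modest noise."""
    cfg = tg.SimulationConfig(
        form="MONOD2", n_species=4, obs_per_species=12, n_traits=2,
        gamma={"alpha": [150.0, 30.0, 0.0], "beta": [8.0, 1.0, 0.0]},
        tau=0.05, sigma=0.15, seed=42,
    )
    dataset, truth = tg.generate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noisefree_dataset():
    """3 species generated exactly on Monod curves (tau=0, near-zero noise)."""
    cfg = tg.SimulationConfig(
        form="MONOD2", n_species=3, obs_per_species=15, n_traits=1,
        gamma={"alpha": [120.0, 25.0], "beta": [6.0, 0.0]},
        tau=0.0, sigma=1e-6, seed=7,
    )
    dataset, truth = tg.generate(cfg)
    return cfg, dataset, truth
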