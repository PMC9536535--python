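import pytest

from orfscreen import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen with planted effects, for fast unit tests."""
    cfg = SimulationConfig(
        n_genes=400,
        n_orfs=4,
        replicates_per_orf=3,
        n_batches=2,
        controls_per_batch=2,
        hits_per_orf=12,
        noise_sd=0.2,
        batch_sd=0.3,
        effect_low=1.5,
        effect_high=3.0,
        seed=11,
    )
    return cfg, simulate_screen(cfg)


@pytest.fixture(scope="session")
def default_screen():
    """One screen at the generator's default study conditions."""
    cfg = SimulationConfig(seed=1)
    return cfg, simulate_screen(cfg)
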