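import numpy as np
import pytest

from lethalscan.synthetic_data import SimConfig, plant_lethal, simulate_founders


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_planted():
    """A 2000-animal founder population with a 13% planted lethal."""
    cfg = SimConfig(n_boars=60, n_sows=1940, n_markers=150,
                    chrom_length_bp=8_000_000, lethal_position_bp=4_000_000,
                    target_carrier_freq=0.13, seed=202)
    rng = cfg.rng()
    founders = simulate_founders(cfg, rng)
    genotypes, lethal = plant_lethal(founders, cfg, rng)
    return cfg, genotypes, lethal
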