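import numpy as np
import pytest

from dupcycles.collinearity import detect_blocks
from dupcycles.dup_classifier import filter_hits
from dupcycles.synthetic_data import SimulationConfig, fabricate_hits, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        n_chromosomes=3,
        n_ancestral_genes=300,
        wgd_events=((0.4, 0.8),),
        n_tandem=15,
        n_proximal=15,
        n_transposed=15,
        n_dispersed=15,
        codon_length=60,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_hits(small_bundle, small_config):
    raw = fabricate_hits(
        small_bundle.genome,
        small_bundle.truth,
        small_bundle.cds,
        spurious_fraction=small_config.spurious_hit_fraction,
        seed=small_config.seed + 1,
    )
    return filter_hits(raw)


@pytest.fixture(scope="session")
def small_blocks(small_bundle, small_hits):
    return detect_blocks(small_bundle.genome, small_bundle.genome, small_hits)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
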