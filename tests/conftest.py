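"""Shared fixtures: a small seeded genome and colony for fast tests."""

import numpy as np
import pytest

from crisprcolony import synthetic_data as sd


@pytest.fixture(scope="session")
def config():
    return sd.GeneratorConfig(genome_length=20_000, read_error_rate=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def genome(config):
    return sd.generate_phage_genome(config)


@pytest.fixture(scope="session")
def plus_starts(genome, config):
    starts = sd.valid_protospacer_starts(genome, config.spacer_length, config.pam)
    return [s for s, st in starts if st == "+"]


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
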