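"""Shared fixtures: small simulated genomes and trait panels."""

import numpy as np
import pandas as pd
import pytest

from ccqtlmed.synthetic_data import SimConfig, simulate_founder_mosaics, assign_batches


@pytest.fixture(scope="session")
def small_config():
    """Two 100 Mb chromosomes, 50 loci each, 47 strains."""
    return SimConfig(chromosomes=(("1", 100.0, 50), ("2", 100.0, 50)), seed=11)


@pytest.fixture(scope="session")
def small_fdm(small_config):
    return simulate_founder_mosaics(small_config)


@pytest.fixture(scope="session")
def small_batch(small_config):
    return assign_batches(small_config.n_strains, small_config.batch_levels,
                          small_config.seed)
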