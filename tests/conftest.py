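"""Shared fixtures: small deterministic synthetic surveys."""

from __future__ import annotations

import numpy as np
import pytest

from peroxscan.insilico_pcr import builtin_primer_pairs
from peroxscan.synthetic_data import SimConfig, generate_pools


@pytest.fixture(scope="session")
def primer_pairs():
    return builtin_primer_pairs()


@pytest.fixture(scope="session")
def small_sim():
    """A 3-site survey with mild (2%) mutation noise."""
    return generate_pools(SimConfig(seed=11, n_sites=3, pool_size=4))


@pytest.fixture(scope="session")
def clean_sim():
    """A zero-noise survey: every call must match truth exactly."""
    return generate_pools(
        SimConfig(seed=23, n_sites=2, pool_size=4, env_mutation_rate=0.0, duplicate_rate=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
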