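"""Shared fixtures: small simulated datasets with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from dnmkit.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 Mb, two 10-sib families, inflated mutation rate for counting power."""
    cfg = SimConfig(
        genome_length=2_000_000,
        n_chroms=2,
        n_families=2,
        sibs_per_clutch=10,
        true_mu=5e-7,
    )
    return simulate_dataset(cfg, 2024)


@pytest.fixture(scope="session")
def three_gen_dataset():
    """3-generation families for transmission and pedigree-shape checks."""
    cfg = SimConfig(
        genome_length=1_000_000,
        n_chroms=2,
        n_families=2,
        pedigree_type="three_gen_inbred",
        sibs_per_clutch=10,
        true_mu=1e-6,
    )
    return simulate_dataset(cfg, 7)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """No artifacts or quality noise: survivors must equal the planted set."""
    cfg = SimConfig(
        genome_length=2_000_000,
        n_chroms=2,
        n_families=2,
        sibs_per_clutch=10,
        true_mu=5e-7,
    ).noise_free()
    return simulate_dataset(cfg, 99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
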