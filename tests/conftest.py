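"""Shared fixtures: one small synthetic trio reused across unit tests."""

import numpy as np
import pytest

from cenevol import synthio


@pytest.fixture(scope="session")
def small_config():
    cfg = synthio.TrioConfig(
        seed=7, n_chromosomes=4, chrom_length=300_000,
        array_length_range=(8_000, 14_000),
        n_insertions=3, n_deletions=3, n_inversions=1,
        tss_count=8, tss_background=20,
        contigs_per_chromosome=8)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_trio(small_config):
    return synthio.generate_trio(small_config)


@pytest.fixture(scope="session")
def small_trio_with_arrays(small_trio):
    return synthio.generate_centromere_arrays(small_trio)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)


def random_dna(rng, n):
    return rng.integers(0, 4, n).astype(np.uint8)
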