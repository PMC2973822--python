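import numpy as np
import pytest

from kircontent import (
    HaplotypeTable,
    LocusRegistry,
    chimp_like_default_spec,
    simulate_haplotype_pool,
)


@pytest.fixture(scope="session")
def two_locus_registry():
    return LocusRegistry(("A", "B"))


@pytest.fixture(scope="session")
def chimp_pool():
    return simulate_haplotype_pool(chimp_like_default_spec(), seed=0)


def make_table(registry, rows):
    """HaplotypeTable from {'presence string': frequency} rows, e.g. {'10': 0.7}."""
    names = tuple(f"h{s}" for s in rows)
    vectors = np.array([[ch == "1" for ch in s] for s in rows], dtype=bool)
    freqs = np.array(list(rows.values()), dtype=float)
    return HaplotypeTable(registry, names, vectors, freqs)


@pytest.fixture(scope="session")
def make_haplotype_table():
    return make_table
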