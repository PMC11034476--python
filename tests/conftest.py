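import numpy as np
import pytest

from aavep import build_matrix, generate_family, generate_variants
from aavep.descriptors import get_table


@pytest.fixture(scope="session")
def z3():
    return get_table("Z3")


@pytest.fixture(scope="session")
def family():
    return generate_family(seed=11)


@pytest.fixture(scope="session")
def strong_matrix(family):
    """Planted strong signal in domain 8 (150 benign / 100 pathogenic)."""
    variants = generate_variants(family, 150, 100, {8}, effect_size=6.0, seed=12)
    return build_matrix(
        family.wildtypes, variants, mode="domainwise", partitions=family.partitions
    )


@pytest.fixture(scope="session")
def null_matrix(family):
    """Same counts, zero effect size: labels carry no signal."""
    variants = generate_variants(family, 150, 100, {8}, effect_size=0.0, seed=12)
    return build_matrix(
        family.wildtypes, variants, mode="domainwise", partitions=family.partitions
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
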