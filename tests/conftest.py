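import numpy as np
import pytest

from chromlink import GenomicRange, InteractionSet
from chromlink.fixtures import (
    FixtureConfig,
    generate_feature_sets,
    generate_interactions,
)


def random_interaction_set(seed: int, n: int = 50, trans_fraction: float = 0.1):
    """Small random InteractionSet for structural tests."""
    cfg = FixtureConfig(seed=seed, n_interactions=n, trans_fraction=trans_fraction)
    iset, _ = generate_interactions(cfg)
    return iset


def brute_force_overlap(a: GenomicRange, b: GenomicRange) -> bool:
    if a.chrom != b.chrom:
        return False
    return not (a.end < b.start or b.end < a.start)


@pytest.fixture
def small_iset():
    """Four pairs with known coordinates, counts and metadata."""
    a1 = [
        GenomicRange("chr1", 100, 200),
        GenomicRange("chr1", 1000, 1100),
        GenomicRange("chr2", 500, 700),
        GenomicRange("chrM", 10, 40),
    ]
    a2 = [
        GenomicRange("chr1", 500, 600),
        GenomicRange("chr2", 1000, 1100),
        GenomicRange("chr2", 9000, 9100),
        GenomicRange("chr1", 50, 80),
    ]
    return InteractionSet(
        a1, a2, [1, 3, 5, 4],
        {"fdr": [0.01, 0.2, 0.01, 0.04], "label": ["a", "b", "c", "d"]},
    )


@pytest.fixture
def default_config():
    return FixtureConfig(seed=7)


@pytest.fixture
def feature_sets(default_config):
    return generate_feature_sets(default_config)
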