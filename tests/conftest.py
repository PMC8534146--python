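import numpy as np
import pandas as pd
import pytest

from fpseg import ContactMatrix, DomainSet, SyntheticSpec, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_domains():
    """Three 2-bin domains at 40 kb: F1 [0,80k), F2 [80k,160k), P1 [160k,240k)."""
    return DomainSet.from_intervals(
        "chr1", [(0, 80_000), (80_000, 160_000), (160_000, 240_000)], ["F", "F", "P"])


@pytest.fixture
def small_genome():
    spec = SyntheticSpec(n_domains=10, domain_length_bins=(4, 8))
    return generate_genome(spec, seed=7)


def random_symmetric_matrix(rng, n, resolution_bp=40_000, chrom="chr1"):
    """Strictly positive random symmetric matrix (no masked bins)."""
    a = rng.uniform(0.1, 5.0, size=(n, n))
    v = (a + a.T) / 2
    return ContactMatrix(chrom, resolution_bp, v)


def random_domain_genome(rng, n_domains=40, min_bins=2, max_bins=8, resolution_bp=40_000):
    """Random F/P domain set on one chromosome with random labels."""
    lengths = rng.integers(min_bins, max_bins + 1, size=n_domains) * resolution_bp
    ends = np.cumsum(lengths)
    starts = np.concatenate([[0], ends[:-1]])
    labels = rng.choice(["F", "P"], size=n_domains)
    # ensure both types occur
    labels[0], labels[1] = "F", "P"
    return DomainSet.from_intervals("chr1", list(zip(starts, ends)), labels)
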