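import numpy as np
import pandas as pd
import pytest

from cytoscan import GenomeMap, synthetic_genome


@pytest.fixture(scope="session")
def small_genome() -> GenomeMap:
    """3 chromosomes x 2 arms x 2 bands x 30 SNPs: fast but window-compatible."""
    return synthetic_genome(n_chroms=3, bands_per_arm=2, snps_per_band=30)


@pytest.fixture(scope="session")
def full_genome() -> GenomeMap:
    """The default 22-chromosome synthetic map (shared; treat as read-only)."""
    return synthetic_genome()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_scores(rng, n_samples=8, bands=("1p2", "1p1", "1q1", "1q2"), scale=5.0):
    """Random score matrix with genome-order band columns."""
    return pd.DataFrame(
        rng.normal(0.0, scale, (n_samples, len(bands))),
        index=[f"s{i:02d}" for i in range(n_samples)],
        columns=list(bands),
    )
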