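import numpy as np
import pandas as pd
import pytest

from haploclust.datasets import GenotypeDataset


def make_dataset(dosages, phenotype=None, chrom="1", positions=None, ids=None):
    """Build a small GenotypeDataset from a dosage matrix (samples x variants)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    ids = ids if ids is not None else [f"rs{j}" for j in range(m)]
    variants = pd.DataFrame({
        "id": ids, "chrom": chrom, "pos": positions, "a1": "A", "a2": "G",
    })
    return GenotypeDataset(variants, [f"s{i}" for i in range(n)], dosages, phenotype)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def block_panel():
    """A small reference panel with clean block structure (one pattern group
    per block, two founders, no copy noise): within-block r2 is 1."""
    from haploclust.simulate import generate_reference_panel

    return generate_reference_panel(
        n_variants=120, n_hap=100, block_len_mean=8, founders_per_block=2,
        groups_per_block_mean=1.0, copy_noise=0.0, seed=7)


@pytest.fixture(scope="session")
def default_panel():
    """A session-wide default-structure panel for LD/clustering tests."""
    from haploclust.simulate import generate_reference_panel

    return generate_reference_panel(n_variants=400, seed=11)
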