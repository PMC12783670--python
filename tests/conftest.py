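import numpy as np
import pytest

from pausekit import SimConfig, simulate_genome, simulate_rnap2_tracks


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """A small genome that keeps every stage fast but non-degenerate."""
    return SimConfig(
        n_genes=30,
        chrom_length=200_000,
        gene_length_range=(2_000, 4_000),
        n_replicates=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_genes(tiny_cfg):
    return simulate_genome(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_tracks(tiny_cfg, tiny_genes):
    return simulate_rnap2_tracks(tiny_genes, tiny_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
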