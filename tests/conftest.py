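import numpy as np
import pytest

from genepip import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_genome():
    """A small annotation-enriched GWAS genome with ground truth."""
    cfg = sim.SimConfig(seed=7, n_blocks=60, snps_per_block=40)
    return sim.simulate_annotated_genome(cfg)


@pytest.fixture(scope="session")
def small_landscape():
    """A small gene landscape with designated causal genes."""
    cfg = sim.SimConfig(seed=9, n_loci=25)
    return sim.simulate_gene_landscape(cfg)
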