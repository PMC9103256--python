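import numpy as np
import pandas as pd
import pytest

from methtriad.config import PipelineConfig, SimConfig
from methtriad.models import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


@pytest.fixture
def small_calls():
    """Six cytosine calls on one chromosome, all three contexts."""
    return pd.DataFrame({
        "chrom": ["c1"] * 6,
        "pos": [9, 19, 29, 39, 49, 59],
        "strand": ["+", "-", "+", "+", "-", "+"],
        "context": ["CG", "CG", "CG", "CHH", "CHG", "CG"],
        "meth": [3, 5, 10, 1, 0, 0],
        "total": [12, 5, 10, 4, 6, 8],
    })


@pytest.fixture
def plus_gene():
    """A 3-exon gene on the + strand: [1000, 2000) with introns."""
    return GeneModel(
        gene_id="g1", chrom="c1", start=1000, end=2000, strand="+",
        exons=[(1000, 1200), (1400, 1600), (1800, 2000)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic dataset shared by slower integration tests."""
    from methtriad.simulate import simulate_all
    cfg = SimConfig(seed=7, n_chroms=1, chrom_len=400_000, n_genes=30,
                    n_mirna_loci=12, n_planted_dmrs=8, n_planted_degs=8,
                    n_planted_ders=8, n_planted_neg_triads=3,
                    n_distractor_triads=3)
    return simulate_all(cfg)
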