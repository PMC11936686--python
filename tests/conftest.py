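import numpy as np
import pytest

from erosim.genome_model import DFESpec, GenomeArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_arch():
    """Desk-scale exome: 500 genes x 400 bp = 200 kb."""
    return GenomeArchitecture(n_genes=500, gene_length=400, boundary_crossover_prob=1e-4)


@pytest.fixture
def hot_dfe():
    """Mutation rate boosted so toy populations hold measurable variation."""
    return DFESpec(mutation_rate_per_bp=1e-6)


@pytest.fixture
def neutral_dfe():
    return DFESpec(mutation_rate_per_bp=1e-6, p_deleterious=0.0)
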