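import numpy as np
import pytest

from gsindex.architecture import assign_architecture
from gsindex.genome import GenomeConfig, build_genome, compute_tbv, make_f2
from gsindex.experiment import ExperimentConfig


SMALL_GENOME_CFG = GenomeConfig(
    n_chromosomes=3, markers_per_chromosome=40, n_qtl=30, n_le_qtl=2
)


@pytest.fixture(scope="session")
def small_genome():
    return build_genome(SMALL_GENOME_CFG, seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down paired-experiment config for fast end-to-end tests."""
    return ExperimentConfig(
        genome=SMALL_GENOME_CFG,
        qtl_counts=(24, 10, 6, 4),
        n_genotypes=120,
        n_cycles=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def paper_genome():
    """Full-scale genome: 10 chromosomes, 2500 markers, 315 QTL (15 LE)."""
    return build_genome(GenomeConfig(), seed=101)


@pytest.fixture(scope="session")
def paper_architecture(paper_genome):
    cfg = ExperimentConfig()
    return assign_architecture(
        paper_genome,
        cfg.target_matrix(),
        cfg.qtl_counts,
        cfg.heritabilities,
        np.random.default_rng(202),
    )


@pytest.fixture(scope="session")
def paper_f2(paper_genome, paper_architecture):
    pop = make_f2(paper_genome, 500, np.random.default_rng(303))
    compute_tbv(pop, paper_architecture.effects, paper_genome)
    return pop
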