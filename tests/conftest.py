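import numpy as np
import pytest

from grasskit.simulate import (
    F2Spec,
    LtrFamilySpec,
    SimConfig,
    SsrSpec,
    simulate_f2,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_genome():
    """Mixed genome: genes, two LTR families (intact + solo), SSRs."""
    cfg = SimConfig(seed=11, genome_length=600_000, n_chromosomes=2, n_genes=20)
    return cfg, simulate_genome(cfg)


@pytest.fixture(scope="session")
def f2_map_sim():
    """Desk-scale F2 recovery experiment: 7 chromosomes, 500 markers, n=200,
    1% genotyping error, 5% missing data."""
    cfg = SimConfig(
        seed=3,
        genome_length=280_000_000,
        n_chromosomes=7,
        emit_sequence=False,
        f2_spec=F2Spec(
            n_individuals=200,
            n_markers=500,
            crossover_rate=2.0,
            genotype_error_rate=0.01,
            missing_rate=0.05,
        ),
    )
    genome = simulate_genome(cfg)
    return cfg, genome, simulate_f2(cfg, genome)


@pytest.fixture(scope="session")
def repeat_free_config():
    """Genome config without repeats: unique sequence everywhere, so pooled
    reads have a single unambiguous origin."""

    def make(seed: int, genome_length: int = 1_400_000, n_chromosomes: int = 7):
        return SimConfig(
            seed=seed,
            genome_length=genome_length,
            n_chromosomes=n_chromosomes,
            n_genes=20,
            ltr_spec=[],
            ssr_spec=SsrSpec(counts={}),
        )

    return make
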