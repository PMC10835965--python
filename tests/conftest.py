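import pytest

from cropscreen import (
    SimulationParams,
    ToyGenome,
    build_design,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_genome():
    return ToyGenome({"chr1": 30_000_000}, gene_spacing=200_000)


@pytest.fixture(scope="session")
def small_design(small_genome):
    return build_design(
        {"TSS": 6, "ENH": 4}, guides_per_target=4, n_nt=12,
        genome=small_genome, target_spacing=2_500_000,
    )


@pytest.fixture(scope="session")
def small_screen(small_genome, small_design):
    """A 25k-cell screen with 10 targets: shared across unit tests."""
    params = SimulationParams(n_cells=25_000, seed=3)
    return simulate_screen(params, design=small_design, genome=small_genome)
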