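import pytest

from genoloss.synthetic import LossSpec, Simulation, SimulationConfig, demo_tree


@pytest.fixture(scope="session")
def small_tree() -> str:
    return demo_tree(8, depth=0.12, seed=3)


@pytest.fixture(scope="session")
def small_sim(small_tree) -> Simulation:
    """A compact dataset: 60 genes, one internal-branch loss, artifacts on."""
    cfg = SimulationConfig(
        tree=small_tree,
        n_genes=60,
        seed=11,
        loss_events=[
            LossSpec(branch="sp02,sp03", n_genes=3),
            LossSpec(branch="sp06", n_genes=2),
        ],
        splice_shift_fraction=0.05,
        intron_deletion_fraction=0.03,
    )
    return Simulation(cfg)


@pytest.fixture(scope="session")
def clean_sim(small_tree) -> Simulation:
    """No losses, no corruption: every gene should look intact everywhere."""
    cfg = SimulationConfig(
        tree=small_tree,
        n_genes=25,
        seed=5,
        assembly_error_rate=0.0,
        gap_per_mb=0.0,
        near_gap_errors=0.0,
        indel_rate=0.0,
    )
    return Simulation(cfg)
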