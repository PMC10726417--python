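import pytest

from ohnotype.synthetic_data import (
    SimulationConfig,
    default_species_tree,
    simulate,
)


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulation shared across the suite."""
    return simulate()


@pytest.fixture(scope="session")
def default_inference(default_sim):
    from ohnotype.reporting_cli import run_inference

    genomes, calls = run_inference(default_sim)
    return genomes, calls


@pytest.fixture()
def quiet_config():
    """All event rates zero: genomes pass through the tree unchanged."""
    return SimulationConfig(
        tandem_duplication_rate=0.0,
        dispersed_duplication_rate=0.0,
        gene_loss_rate=0.0,
        inversion_rate=0.0,
        translocation_rate=0.0,
        fusion_prob=0.0,
        fission_prob=0.0,
        cds_substitution_rate=0.0,
        pseudogenize_prob=0.0,
        n_families=20,
        n_chromosomes=3,
        cluster_templates={"Hox": 6},
    )
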