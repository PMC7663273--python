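import pytest
from hypothesis import HealthCheck, settings

from fuzzypcm import (
    FixtureSpec,
    LigandStructure,
    build_dataset,
    generate_fixture,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


SMALL_SPEC = FixtureSpec(
    n_proteins=12,
    n_ligands=24,
    n_classes=3,
    seq_len=60,
    motif_len=10,
    n_neg_per_ligand=4,
    seed=7,
)


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale synthetic benchmark shared across tests."""
    return generate_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_dataset(small_fixture):
    """Curated dataset of the small benchmark."""
    structures = [
        LigandStructure.from_smiles(lid, smi)
        for lid, smi in sorted(small_fixture.smiles.items())
    ]
    return build_dataset(
        small_fixture.records,
        small_fixture.sequences,
        structures,
        small_fixture.spec.parameter,
        small_fixture.spec.cutoff_umol,
    )
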