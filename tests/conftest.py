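import pytest

from dhaaxl.chem import builtin_modifications
from dhaaxl.simulate import (
    SimulationParams,
    generate_proteome,
    plant_modifications,
)


@pytest.fixture(scope="session")
def mods():
    return builtin_modifications()


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted ground truth shared across search/stats tests."""
    params = SimulationParams(
        seed=11,
        n_proteins=20,
        n_direct_sites=6,
        n_conjugate_sites=3,
        n_crosslinks_intra=4,
        n_crosslinks_inter=4,
        n_crosslinks_light_only=2,
        n_background_peptides=30,
    )
    return plant_modifications(generate_proteome(params))
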