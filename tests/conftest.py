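import pytest

from cdclmine import PlantSpec, generate_genomes


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-genome set shared by discovery-level tests."""
    return generate_genomes(PlantSpec(n_genomes=12, seed=11))
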