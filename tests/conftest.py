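import pytest

from directppi import synthetic


@pytest.fixture(scope="session")
def small_world():
    """20 chain complexes of 5-8 subunits at the default planted rates."""
    return synthetic.make_world(n_complexes=20, size_range=(5, 8), seed=7)


@pytest.fixture(scope="session")
def small_compendium(small_world):
    return synthetic.simulate_compendium(small_world, 300, seed=8)
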