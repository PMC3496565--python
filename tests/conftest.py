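import pytest

from baculokit import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_genome():
    """One study-condition synthetic genome plus its exact truth table."""
    recipe = sd.default_recipe(seed=1, length=40_000)
    return sd.make_genome(recipe)
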