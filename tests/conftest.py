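import pytest

import mealopt as mo


@pytest.fixture(scope="session")
def comp31():
    """The packaged 31-category breakfast-like composition matrix."""
    return mo.generate_composition(1, 31, "paper_like")


@pytest.fixture(scope="session")
def calcium():
    """(composition, observed pattern, guidelines) of the two-food calcium problem."""
    return mo.fixture_calcium_example()


@pytest.fixture(scope="session")
def calcium_problem(calcium):
    comp, obs, gl = calcium
    return mo.DeviationLP.from_guidelines(obs, comp, gl, "adults")


@pytest.fixture(scope="session")
def t1_children():
    return mo.fixture_t1_breakfast("children")


@pytest.fixture(scope="session")
def t1_adults():
    return mo.fixture_t1_breakfast("adults")


@pytest.fixture(scope="session")
def population(comp31):
    """A 200-person synthetic intake population with 25% breakfast skippers."""
    return mo.generate_population(7, 200, 0.25, comp31)
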