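import pytest

import rctsim


@pytest.fixture(scope="session")
def model():
    return rctsim.RctModel()


@pytest.fixture(scope="session")
def posterior():
    return rctsim.load_fixtures("posterior_nominal")


@pytest.fixture(scope="session")
def nominal_steady(model, posterior):
    return model.steady_state(posterior)


@pytest.fixture(scope="session")
def population_table():
    """Reference virtual population: 2000 subjects, 15% relative SD, seed 1."""
    spec = rctsim.PopulationSpec(n_subjects=2000, relative_sd=0.15, seed=1)
    return rctsim.simulate_population(rctsim.sample_population(spec))
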