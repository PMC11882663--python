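import numpy as np
import pytest

from bsemfit.gibbs_sampler import McmcSettings, sample_posterior
from bsemfit.population_models import as_analysis_model, build_generation_model
from bsemfit.priors import make_prior
from bsemfit.synthetic_data import generate


@pytest.fixture(scope="session")
def model_a85():
    return build_generation_model("A", 0.85)


@pytest.fixture(scope="session")
def model_a35():
    return build_generation_model("A", 0.35)


@pytest.fixture(scope="session")
def model_b05():
    return build_generation_model("B", cross_loading_value=0.5)


@pytest.fixture(scope="session")
def fast_settings():
    """Short chains for structural tests that do not assert posterior accuracy."""
    return McmcSettings(min_iterations=400, max_iterations=800, seed=0)


@pytest.fixture(scope="session")
def a1_fit(model_a85):
    """A correctly specified 3-factor fit with a diffuse prior at n = 500,
    shared by the tests that only inspect posterior structure."""
    analysis = as_analysis_model(model_a85)
    data = generate(model_a85, 500, seed=42)
    prior = make_prior("Diffuse", model_a85, analysis)
    settings = McmcSettings(min_iterations=800, max_iterations=1600, seed=3)
    draws = sample_posterior(data, analysis, prior, settings)
    return {"generation": model_a85, "analysis": analysis, "data": data,
            "prior": prior, "draws": draws}
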