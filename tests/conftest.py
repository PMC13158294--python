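import warnings

import pytest

import polarnet as pn
from polarnet import synthdata

PLANTED_COUNTS = {
    "TaCAT1": 6,
    "TaHSP70": 5,
    "TaPEX11.4": 3,
    "TaSOD": 3,
    "TaPEX11.3": 3,
    "TaFIS1A": 2,
    "TaDRP5B": 2,
    "TaHSP90": 0,
}

PLANTED_ROLES = {
    "TaHSP70": "hub",
    "TaCAT1": "hub",
    "TaPEX11.4": "hub",
    "TaSOD": "phenotypic_switcher",
    "TaDRP5B": "phenotypic_switcher",
    "TaHSP90": "contextual_responder",
    "TaPEX11.3": "contextual_responder",
    "TaFIS1A": "contextual_responder",
}


@pytest.fixture(scope="session")
def design():
    return pn.StudyDesign()


@pytest.fixture(scope="session")
def truth(design):
    return pn.paper_like_truth(design)


@pytest.fixture(scope="session")
def study(design, truth):
    """One noisy realisation at the packaged-fixture seed."""
    return pn.generate_study(design, truth, seed=synthdata.PAPER_LIKE_SEED)


@pytest.fixture(scope="session")
def noiseless_study(design, truth):
    return pn.generate_study(design, truth.with_noise(0.0, 0.0), seed=0)


@pytest.fixture(scope="session")
def expression(study):
    ct, _, _ = study
    return pn.quantify(ct, "Actin-7")


@pytest.fixture(scope="session")
def fitted_network(expression, study):
    _, traits, _ = study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pn.DifferentialNetwork().fit(expression, traits)
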