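import pytest

from lungscreen.params import default_parameters, sensitivity_ranges
from lungscreen.synthetic import default_life_table

COHORTS = [("japan", "male"), ("japan", "female"), ("us", "male"), ("us", "female")]


@pytest.fixture(scope="session", params=COHORTS, ids=lambda c: f"{c[0]}_{c[1]}")
def cohort(request):
    return request.param


@pytest.fixture(scope="session")
def params_jm():
    return default_parameters("japan", "male")


@pytest.fixture(scope="session")
def params_um():
    return default_parameters("us", "male")


@pytest.fixture(scope="session")
def table_jm(params_jm):
    return default_life_table(params_jm)


@pytest.fixture(scope="session")
def table_um(params_um):
    return default_life_table(params_um)


@pytest.fixture(scope="session")
def all_cohorts():
    out = {}
    for country, sex in COHORTS:
        ps = default_parameters(country, sex)
        out[f"{country}_{sex}"] = (ps, default_life_table(ps), sensitivity_ranges(ps))
    return out
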