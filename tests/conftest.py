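import pytest

from lcscea.cohort_tree import simulate_arms
from lcscea.parameters import table1_fixture
from lcscea.pipeline import run_model_with_ledger
from lcscea.synthetic_data import make_life_table, make_screening_outcomes


@pytest.fixture(scope="session")
def base_params():
    return table1_fixture()


@pytest.fixture(scope="session")
def default_som():
    return make_screening_outcomes()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def base_ledger(base_params, default_som, life_table):
    return simulate_arms(base_params, default_som, life_table)


@pytest.fixture(scope="session")
def base_run(base_params, default_som, life_table):
    """(EconomicResult, DiagnosisLedger) for the shipped defaults."""
    return run_model_with_ledger(base_params, default_som, life_table)


@pytest.fixture(scope="session")
def base_result(base_run):
    return base_run[0]
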