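import numpy as np
import pandas as pd
import pytest

from intrinsol.descriptors import compute_descriptors
from intrinsol.fixtures import TOY_MOLECULES, DRUG_MOLECULES, challenge_outlier_predictions


@pytest.fixture
def rng():
    return np.random.default_rng(20221021)


@pytest.fixture(scope="session")
def toy_smiles():
    return dict(TOY_MOLECULES)


@pytest.fixture(scope="session")
def all_fixture_smiles():
    return {**TOY_MOLECULES, **DRUG_MOLECULES}


@pytest.fixture(scope="session")
def toy_descriptor_matrix():
    matrix, failures = compute_descriptors(TOY_MOLECULES.items())
    assert not failures
    return matrix


@pytest.fixture(scope="session")
def outlier_table() -> pd.DataFrame:
    return challenge_outlier_predictions()
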