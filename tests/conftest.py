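import numpy as np
import pandas as pd
import pytest

from toxcp.chemprep import ActivityMatrix
from toxcp.fixtures import molecule_library


@pytest.fixture(scope="session")
def library():
    return molecule_library()


@pytest.fixture(scope="session")
def corpus50(library):
    """50 deterministic standardised molecules spread over the library."""
    step = max(1, len(library) // 50)
    return list(library[::step][:50])


@pytest.fixture()
def toy_matrix():
    """Tiny activity matrix: 4 compounds, 2 endpoints, one never-tested
    compound present in the corpus."""
    values = pd.DataFrame([
        {"compound_id": "a", "endpoint": "e1", "label": 1},
        {"compound_id": "a", "endpoint": "e2", "label": 0},
        {"compound_id": "b", "endpoint": "e1", "label": 0},
        {"compound_id": "c", "endpoint": "e1", "label": 1},
        {"compound_id": "c", "endpoint": "e2", "label": 1},
        {"compound_id": "c", "endpoint": "e3", "label": 0},
    ])
    structures = {"a": "CCO", "b": "c1ccccc1", "c": "CCN", "d": "CCCC"}
    return ActivityMatrix(
        compounds=["a", "b", "c"],
        endpoints=["e1", "e2", "e3"],
        values=values,
        structures=structures,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
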