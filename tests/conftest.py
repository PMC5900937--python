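import numpy as np
import pytest

from screenmine.synthetic import study_default_config, worked_fixture
from screenmine.transactions import TransactionMatrix


@pytest.fixture
def fixture_f1() -> TransactionMatrix:
    """10 patients x 3 items with hand-checkable supports (a=.8, b=.9, c=.2)."""
    return worked_fixture()


@pytest.fixture(scope="session")
def study_cohort():
    """Study-default synthetic cohort at n=100 000, shared across tests."""
    import screenmine.synthetic as syn

    config = study_default_config(n=100_000, seed=20240)
    return config, syn.generate(config)


def random_matrix(rng: np.random.Generator, n: int, m: int,
                  density: float = 0.5) -> TransactionMatrix:
    values = (rng.random((n, m)) < density).astype(np.uint8)
    items = tuple(f"i{j:02d}" for j in range(m))
    return TransactionMatrix.from_arrays(values, items)
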