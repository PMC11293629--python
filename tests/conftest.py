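import numpy as np
import pytest

from pcmer import generate_class_dataset, random_class_models


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_class_dataset():
    """Small well-separated 2-class Markov dataset shared across modules."""
    models = random_class_models(2, seed=101)
    return generate_class_dataset(models, n_per_class=20, length=300, seed=102)
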