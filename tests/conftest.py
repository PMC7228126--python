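import numpy as np
import pytest

from pseterm import (
    Dataset,
    SequenceRecord,
    SimulationConfig,
    load_property_table,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def table():
    return load_property_table()


@pytest.fixture(scope="session")
def synthetic_small():
    """A small separable synthetic benchmark (40 + 40, fixed seed)."""
    return simulate_dataset(SimulationConfig(n_pos=40, n_neg=40, seed=7))


@pytest.fixture()
def tiny_dataset():
    return Dataset(
        [
            SequenceRecord("a", "ACGTACGT", "positive"),
            SequenceRecord("b", "GGGCCCAT", "negative"),
            SequenceRecord("c", "TTTTACGT", "positive"),
        ],
        name="tiny",
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
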