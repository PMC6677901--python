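import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from subgroupscope.sequence_io import Alignment, SequenceRecord, load_matrix
from subgroupscope.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def blosum30():
    return load_matrix("BLOSUM30")


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (k=3, n=50/subgroup, seed 1)."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast per-module tests."""
    return generate_dataset(GeneratorConfig(n_per_subgroup=15, domain_length=150, seed=7))


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(SequenceRecord(i, s) for i, s in rows.items()))


@pytest.fixture
def toy_alignment():
    return make_alignment(
        {
            "a": "ACDE-FGH",
            "b": "ACDE-FGH",
            "c": "AC-EKFGH",
        }
    )
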