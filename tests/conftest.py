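import numpy as np
import pytest
from hypothesis import settings

from mfescan import (
    ModelConfig,
    SyntheticConfig,
    assemble_dataset,
    generate,
    train_pair,
)
from mfescan.sequence_io import STANDARD_AA, ProteinRecord

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: fast hyperparameters for tests that exercise behaviour, not performance
FAST_CONFIG = ModelConfig(grid_search=False, svm_c=4.0, svm_gamma="scale", rf_trees=100)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture(scope="session")
def biased_proteins():
    """Charged-residue-biased synthetic proteins, 40 per class."""
    return generate(SyntheticConfig(n_per_class=40, seed=11))


@pytest.fixture(scope="session")
def biased_dataset(biased_proteins):
    pos = [p for p in biased_proteins if p.is_mfe]
    neg = [p for p in biased_proteins if not p.is_mfe]
    return assemble_dataset(pos, neg)


@pytest.fixture(scope="session")
def trained_pair(biased_dataset):
    return train_pair(biased_dataset, config=FAST_CONFIG, seed=11)


@pytest.fixture
def toy_records():
    return [
        ProteinRecord(id="p1", sequence="MKVLDE"),
        ProteinRecord(id="p2", sequence="ACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord(id="p3", sequence="KKDDKKDD"),
    ]
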