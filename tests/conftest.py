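import numpy as np
import pytest

from sharkdive import (MutationParams, build_training_pairs, generate_dataset,
                       split_by_family, train_dive)
from sharkdive.physchem import ALPHABET


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_dataset():
    """12 compact families: enough structure to learn, fast to build."""
    return generate_dataset(
        n_families=12, members_range=(3, 5), length_range=(40, 80),
        n_motifs=2, motif_length_range=(6, 9),
        params=MutationParams(seed=5), seed=5)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_by_family(small_dataset, seed=5)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_split):
    train_fams = [f for f in small_dataset
                  if f.family_id in small_split.train]
    pairs = build_training_pairs(train_fams, seed=5)
    return train_dive(pairs, n_submodels=5, seed=5)
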