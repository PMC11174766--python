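import itertools

import numpy as np
import pytest

import foldclust as fc
from foldclust.synthetic import random_segments


@pytest.fixture(scope="session")
def small_dataset():
    """3 families x 4 members, L=60, sigma=0.3: fast shared ground-truth set."""
    spec = fc.SyntheticFamilySpec(
        n_families=3, members_per_family=4, length=60, sigma=0.3,
        indel_rate=0.1, seed=11,
    )
    return fc.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_alignments(small_dataset):
    """All-pairs alignment results on the small dataset (computed once)."""
    structs = small_dataset.structures.structures
    return {
        (A.id, B.id): fc.structural_align(A, B)
        for A, B in itertools.combinations(structs, 2)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_random_fold(length: int, seed: int | np.random.Generator) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return fc.make_fold(random_segments(length, rng), rng)
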