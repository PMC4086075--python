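import numpy as np
import pytest

from loctree.classes import DomainOfLife
from loctree.hierarchical import default_tree_spec, train_tree
from loctree.profile_kernel import KernelParams
from loctree.records import ProfileSource, SequenceProfile
from loctree.synthetic import ScenarioConfig, make_dataset


def random_profile(rng: np.random.Generator, length: int,
                   pid: str = "rand") -> SequenceProfile:
    """Random profile with scores on the internal [0, ceiling) scale."""
    scores = rng.uniform(0.0, 6.9, size=(length, 20))
    return SequenceProfile(pid, scores, ProfileSource.FABRICATED)


@pytest.fixture(scope="session")
def archaea_dataset():
    """Small 3-class scenario: quick to train, fully separable."""
    return make_dataset(ScenarioConfig(
        domain_of_life=DomainOfLife.ARCHAEA,
        n_per_class=6,
        n_reference_per_class=10,
        seq_len_range=(100, 140),
        homolog_fraction=0.5,
        seed=11,
    ))


@pytest.fixture(scope="session")
def archaea_model(archaea_dataset):
    ds = archaea_dataset
    spec = default_tree_spec(DomainOfLife.ARCHAEA)
    return train_tree(ds.reference_profiles, ds.reference_truth, spec,
                      KernelParams(k=3))
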