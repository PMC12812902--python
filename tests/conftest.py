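import numpy as np
import pytest

from clegrade.backbone import BackboneSpec
from clegrade.experiments import desk_config, features_from_sequences
from clegrade.synthetic import (
    generate_dataset,
    high_grade_profile,
    low_grade_profile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """4 cases x 2 sequences of separated grade profiles, 64 px, 10 frames."""
    seqs, anns, manifest = generate_dataset(
        4, 2, 0.5, desk_config(), seed=99,
        profiles=(high_grade_profile(), low_grade_profile()))
    return seqs, anns, manifest


@pytest.fixture(scope="session")
def small_features(small_dataset):
    seqs, _, _ = small_dataset
    spec = BackboneSpec(family="tiny_test_cnn", input_size=64, seed=7)
    return features_from_sequences(seqs, spec)
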