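import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuropid import classifier, feature_extraction, synth_data
from neuropid.sequence_io import CANONICAL_AA, ProteinSequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRAIN_SEED = 11
TEST_SEED = 12


def random_sequence(rng: np.random.Generator, length: int) -> ProteinSequence:
    residues = "".join(rng.choice(list(CANONICAL_AA), size=length))
    return ProteinSequence(id=f"rnd{length}", description="", residues=residues)


@pytest.fixture(scope="session")
def train_sets():
    """Default-condition synthetic study sets: 200 positives, 200 pooled
    negatives."""
    return synth_data.training_sets(200, 200, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained(train_sets):
    """One shared ensemble trained under the default study conditions."""
    pos, neg = train_sets
    Xp = feature_extraction.extract_matrix(pos)
    Xn = feature_extraction.extract_matrix(neg)
    bundle, cv = classifier.train(Xp, Xn, seed=TRAIN_SEED)
    return bundle, cv


@pytest.fixture(scope="session")
def fresh_test_sets():
    """Held-out sets from a different seed than the trained bundle."""
    return synth_data.training_sets(200, 200, seed=TEST_SEED)
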