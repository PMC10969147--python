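import numpy as np
import pytest

from bfenet.data_model import DatasetRegistry, FeatureSample, normalize_per_subject
from bfenet.model import BFENet, ModelConfig, TINY_CONFIG
from bfenet.synthetic import PlantedModel, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_registry(n_subjects=3, n_sessions=1, trials=6, n_channels=8, T=32,
                   alpha=2.0, seed=0, n_classes=3):
    model = PlantedModel(
        n_channels=n_channels, n_classes=n_classes, coupling_strength=alpha, seed=seed
    )
    return generate_corpus(model, n_subjects, n_sessions, trials, T)


@pytest.fixture(scope="session")
def tiny_registry():
    """Small planted-connectivity corpus: 3 subjects x 12 trials, 8 channels."""
    return build_registry(n_subjects=3, n_sessions=2, trials=6)


@pytest.fixture(scope="session")
def tiny_registry_normalized(tiny_registry):
    return normalize_per_subject(tiny_registry)


@pytest.fixture(scope="session")
def tiny_net():
    """A built (untrained) network in the desk-scale configuration."""
    cfg = ModelConfig(n_channels=8, n_classes=3, **TINY_CONFIG)
    return BFENet(cfg, T=32, rng=np.random.default_rng(7))


def make_sample(features, subject="s01", session="1", trial="t01", label=0,
                native_length=None):
    features = np.asarray(features, dtype=float)
    return FeatureSample(
        subject_id=subject, session_id=session, trial_id=trial, label=label,
        features=features,
        native_length=features.shape[1] if native_length is None else native_length,
    )
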