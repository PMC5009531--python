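import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A small labeled synthetic corpus shared across tests."""
    from flexc.labels import filter_dataset
    from flexc.synthetic import SyntheticConfig, generate_dataset, label_corpus

    corpus = generate_dataset(SyntheticConfig(n_chains=30, seed=42))
    labeled, _ = filter_dataset(label_corpus(corpus))
    return corpus, labeled


@pytest.fixture(scope="session")
def small_table(small_corpus):
    from flexc.potentials import count_contexts, derive_potentials

    _, labeled = small_corpus
    return derive_potentials(count_contexts(labeled))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
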