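import pytest

from litmap import synthetic
from litmap.clustering import LevelConfig


@pytest.fixture(scope="session")
def small_config():
    """Small planted-topic corpus: quick but structured enough to cluster."""
    return synthetic.SyntheticConfig(n_topics=5, docs_per_topic=30, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return synthetic.generate_corpus(small_config)


@pytest.fixture(scope="session")
def default_corpus():
    """The generator's default config (K=20 x 100, p_within=0.9)."""
    return synthetic.generate_corpus(synthetic.SyntheticConfig(seed=1))


@pytest.fixture
def small_levels():
    return [LevelConfig(5e-3, 10), LevelConfig(5e-4, 30), LevelConfig(5e-5, 60)]
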