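import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import screenstop as ss

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus() -> ss.ScreeningDataset:
    """A 400-document synthetic corpus, 15% relevant, well separable."""
    cfg = ss.SyntheticCorpusConfig(
        N_total=400, prevalence=0.15, separability=1.5, vocabulary_size=200,
        doc_length=30, seed=11,
    )
    return ss.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_config() -> ss.StoppingConfig:
    return ss.StoppingConfig(seed_sample_size=60, batch_size=10, heuristic_window=25)


@pytest.fixture(scope="session")
def small_traces(small_corpus, small_config):
    """Three full screening runs on the small corpus, all criteria enabled."""
    X = ss.featurize(small_corpus)
    return [
        ss.run_screening(small_corpus, small_config, seed=s, features=X)
        for s in (0, 1, 2)
    ]
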