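import numpy as np
import pytest

from siecv import (GeneratorConfig, ModelSpec, PredictorSpec, generate,
                   main_term)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_clustered():
    """5 clusters x 120 participants, one real predictor and one noise."""
    cfg = GeneratorConfig(
        K=5, cluster_sizes=120, mu_alpha=-1.0, sigma_alpha=0.2,
        predictors=(
            PredictorSpec("signal", mu_beta=1.0, tau=0.0),
            PredictorSpec("noise", mu_beta=0.0, tau=0.0),
        ),
        seed=42,
    )
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture
def two_candidate_spec():
    return ModelSpec([], set(), [main_term("signal"), main_term("noise")])
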