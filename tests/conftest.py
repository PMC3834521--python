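import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import analogynet as an
from analogynet.experiments import ExperimentConfig, simulation1, simulation2

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_protoset():
    return an.generate_prototypes(an.RelationSpaceConfig(seed=7))


@pytest.fixture(scope="session")
def small_env():
    """Two-group environment: 10 cells, 30 questions, 570 trials/epoch."""
    return an.build_environment(an.EnvironmentConfig(n_groups=2, seed=5))


@pytest.fixture(scope="session")
def mini_trained(small_env):
    """A network trained to competence on the small environment.

    The small environment has far fewer trials per epoch than the default
    one, so the fixture uses a stronger learning rate and smaller batches to
    reach a comparable amount of training in a few seconds.
    """
    cfg = an.network_config_for(small_env.config, seed=3, lr=0.05, batch_size=16)
    w = an.init_network(cfg)
    w, history = an.train(w, small_env, cfg, epochs=400)
    return w, cfg, history


@pytest.fixture(scope="session")
def study():
    """The full developmental + lesion study at the default operating point.

    Five independently seeded networks, each trained 350 epochs on its own
    generated environment and probed every 10 epochs, then lesioned. Shared
    across the acceptance tests because it is the expensive part of the
    suite.
    """
    cfg = ExperimentConfig(seed=1)
    sim1 = simulation1(cfg)
    lesions = simulation2(cfg, sim1)
    return cfg, sim1, lesions
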