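import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

settings.register_profile(
    "ojipkit",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # fixtures used under @given here are read-only inputs
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ojipkit")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noise_free_transient():
    """Default-spec transient with no noise (targets 0.15/0.35/0.65)."""
    from ojipkit.synth import TransientSpec, generate_transient

    return generate_transient(TransientSpec(noise_cv=0.0), seed=0)


@pytest.fixture(scope="session")
def flooding_study(tmp_path_factory):
    """One generated flooding study, shared across tests (seed 7)."""
    from ojipkit.synth import flooding_preset, generate_study

    root = tmp_path_factory.mktemp("flooding")
    return generate_study(flooding_preset(), root, seed=7)
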