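import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but non-degenerate multi-subject simulation shared across tests."""
    from fmica import SimConfig, synthesize_dataset

    cfg = SimConfig(
        n_subjects=4, grid_side=36, n_sources=4, n_timepoints=60,
        n_blocks=2, task_sources=((1, 4.0, 0.2),), seed=42,
    )
    subjects, truth = synthesize_dataset(cfg)
    return cfg, subjects, truth
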