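import numpy as np
import pytest

import ordimpute as oi


@pytest.fixture(scope="session")
def registry():
    return oi.build_default_registry()


@pytest.fixture(scope="session")
def small_registry(registry):
    """First eight items (SNAP-IV parent 1-8) for cheap end-to-end runs."""
    return oi.subset_registry(registry, n_items=8)


def cheap_hyperparams(seed=0, **overrides):
    """Full-batch settings tuned for speed in small test problems."""
    kw = dict(
        patience_epochs=10,
        dropout_rate=0.0,
        batch_mode=oi.BatchMode.FULL_BATCH,
        max_epochs=300,
        learning_rate=1e-2,
        n_init_attempts=1,
        seed=seed,
    )
    kw.update(overrides)
    return oi.HyperParams(**kw)


@pytest.fixture
def tiny_cohort(small_registry):
    """Complete 60-participant cohort over the 8-item registry."""
    config = oi.CohortConfig(n_case=40, n_control=20, seed=7)
    return oi.generate_cohort(small_registry, config)
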