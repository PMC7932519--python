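import numpy as np
import pandas as pd
import pytest

import esmnet as en


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group Likert cohort at reduced size (10 families per group)."""
    panel, meta, truth = en.simulate_cohort(
        [en.stable_config(n_families=10), en.increase_config(n_families=10)],
        seed=42,
    )
    return panel, meta, truth


@pytest.fixture(scope="session")
def small_design(small_cohort):
    panel, meta, truth = small_cohort
    kept, _ = en.filter_by_missingness(panel, scheduled_beeps=60)
    design, means = en.make_lag_design(kept)
    labels = meta.set_index("person_id")["true_group"]
    return design, labels, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Continuous-observation cohort without missingness (one group)."""
    panel, meta, truth = en.simulate_cohort(
        [en.stable_config(n_families=12, missing_rate=0.0, observe="continuous")],
        seed=7,
    )
    return panel, meta, truth


def random_network(seed, sparsity=0.5, scale=0.2):
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, scale, size=(6, 6))
    W[rng.random((6, 6)) < sparsity] = 0.0
    return W
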