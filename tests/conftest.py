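import numpy as np
import pytest

import rp3d


@pytest.fixture(scope="session")
def small_truth():
    """Seeded diploid polymer small enough for fast per-test pipelines."""
    return rp3d.simulate_polymer(n_chroms=1, beads_per_chain=120,
                                 two_alleles=True, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_truth):
    """Fully detected, fully phased contacts at ~8% recurrence rate."""
    thr = rp3d.threshold_for_recurrence_rate(small_truth, 0.08)
    return rp3d.derive_contacts(small_truth, thr, q_detect=1.0,
                                phasing_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def small_embedding(small_experiment, small_truth):
    return rp3d.reconstruct_cell(small_experiment.contacts,
                                 resolution=small_truth.resolution)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
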