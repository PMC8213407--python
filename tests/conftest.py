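import numpy as np
import pytest
from hypothesis import settings

import oriturn as ot

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

# Reduced study conditions used throughout the suite: the paper-scale rates
# on a 2 Mbp circular genome (stationary count ~44 origins) keep run times
# short while preserving the per-origin dynamics.
SMALL_L = 2_000_000


@pytest.fixture(scope="session")
def rate_dist():
    return ot.synthetic_rate_distribution(seed=123)


@pytest.fixture(scope="session")
def small_params():
    return ot.ModelParams(length_bp=SMALL_L)


@pytest.fixture(scope="session")
def small_run(small_params, rate_dist):
    """One stationary joint-model lineage at reduced scale, reused widely."""
    rng = np.random.default_rng(42)
    return ot.simulate_lineage(
        small_params,
        rate_dist,
        t_total=50.0,
        burn_in=20.0,
        n0=44,
        rng=rng,
    )


@pytest.fixture(scope="session")
def small_table(small_run):
    """Classified-origin table from consecutive snapshots of small_run."""
    return ot.classified_origin_table(
        ot.snapshot_classifications(small_run), small_run.params.kinetic
    )
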