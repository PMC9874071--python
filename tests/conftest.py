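import numpy as np
import pytest
from hypothesis import settings

import tuneplast as tp
from tuneplast.synth import DEFAULT_N_UNITS

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return tp.default_grid()


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect cohort at study trial counts (10 blocks), 4 units/cell."""
    cfg = tp.CohortConfig(
        n_units={c: 4 for c in DEFAULT_N_UNITS},
        effects={c: tp.PairingEffect() for c in DEFAULT_N_UNITS},
        n_blocks=10, seed=101,
    )
    trials, truth = tp.simulate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def null_cohort_fits(null_cohort):
    """Fits table + per-unit results for the shared null cohort."""
    _, trials, truth = null_cohort
    fits, per_unit = tp.pipeline.fit_all_units(trials, tp.RunConfig(seed=101))
    return fits, per_unit, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
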