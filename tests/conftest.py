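import warnings

import numpy as np
import pandas as pd
import pytest

from gaitsym import preprocess, symmetry, synthetic_grf

# Non-converged SMO fits are an expected condition on overlapping classes at
# large C; tests assert on model quality, not on warning emission.
warnings.filterwarnings("ignore", message="SMO stopped", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_fatigue_dataset():
    """In-memory 6-subject dominance+fatigue dataset with default noise."""
    trials = list(synthetic_grf.simulate_trials(
        n_subjects=6, n_trials=2,
        asymmetry=synthetic_grf.fatigue_profile(),
        noise=synthetic_grf.NoiseSpec(), seed=42,
    ))
    return trials


@pytest.fixture(scope="session")
def small_curves(small_fatigue_dataset) -> pd.DataFrame:
    return preprocess.preprocess_dataset(small_fatigue_dataset)


@pytest.fixture(scope="session")
def small_sf(small_curves) -> pd.DataFrame:
    return symmetry.sf_table(symmetry.sf_dataset(small_curves))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230307)
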