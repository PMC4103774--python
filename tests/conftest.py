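import numpy as np
import pytest

import dfa7


@pytest.fixture(scope="session")
def iid_sequence():
    """Long i.i.d. uniform sequence (uncorrelated-walk regime)."""
    cfg = dfa7.GeneratorConfig(length=32768, seed=7)
    return dfa7.generate_iid_sequence(cfg)


@pytest.fixture(scope="session")
def persistent_sequence():
    """Long persistent Markov sequence (correlated regime), same seed."""
    cfg = dfa7.GeneratorConfig(length=32768, persistence=0.95, seed=7)
    return dfa7.generate_persistent_sequence(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two 7-d Gaussian clusters with mean separation 10x the spread."""
    geom = dfa7.ClassGeometry()
    dist = float(np.linalg.norm(np.array(geom.mean_pos) - np.array(geom.mean_neg)))
    geom10 = dfa7.ClassGeometry(spread=dist / 10)
    X, y = dfa7.generate_labeled_features(250, 250, geom10, seed=11)
    return X, y


#: Small tuning grids used where the test only needs a working optimum,
#: not an exhaustive search.
SMALL_C_GRID = (0.25, 4.0, 64.0)
SMALL_GAMMA_GRID = (2.0**-6, 2.0**-3, 1.0)


@pytest.fixture(scope="session")
def small_grids():
    return SMALL_C_GRID, SMALL_GAMMA_GRID
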