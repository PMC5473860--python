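import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fdtraitkit import (CommunityMatrix, TraitMatrix, fixture_small,
                        standardize_traits)


@pytest.fixture(scope="session")
def small_fixture():
    return fixture_small()


@pytest.fixture(scope="session")
def small_std(small_fixture):
    tm, cm = small_fixture
    return standardize_traits(tm), cm


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_tm(rng):
    """20 species x 6 traits, standardized, mild correlation."""
    base = rng.standard_normal((20, 3))
    X = np.hstack([base, base @ rng.standard_normal((3, 3)) * 0.5
                   + rng.standard_normal((20, 3))])
    tm = TraitMatrix([f"sp{i}" for i in range(20)],
                     [f"t{j}" for j in range(6)], X)
    return standardize_traits(tm)
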