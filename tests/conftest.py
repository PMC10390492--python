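import numpy as np
import pytest

import stcomm as st
from stcomm.io import lognormalize


@pytest.fixture(scope="session")
def demo_atlas():
    return st.simulate_preset("coloc-demo", seed=11)


@pytest.fixture(scope="session")
def demo_lognorm(demo_atlas):
    return lognormalize(demo_atlas.expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_lognorm():
    """Tiny deterministic lognorm matrix for scoring unit tests."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(5.0, size=(30, 12))
    counts[0] += 1  # keep totals positive
    em = st.ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(30)],
        [f"s{i}" for i in range(12)],
        layer="raw_counts",
    )
    return lognormalize(em)
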