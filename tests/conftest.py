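import numpy as np
import pytest

import sleepcost as sc


@pytest.fixture(scope="session")
def elephant_wild():
    return sc.preset("elephant_wild")


@pytest.fixture(scope="session")
def elephant_captive():
    return sc.preset("elephant_captive")


@pytest.fixture(scope="session")
def sloth_wild():
    return sc.preset("sloth_wild")


@pytest.fixture(scope="session")
def small_bank():
    # enough draws for 30 days at q=144 plus burn-in
    return sc.make_draw_bank(144 * 60, seed=20240901)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(777)
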