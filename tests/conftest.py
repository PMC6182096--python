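import numpy as np
import pytest

import microcount as mc


@pytest.fixture(scope="session")
def calgary():
    """The packaged eight-sample Giardia monitoring dataset."""
    return mc.load_fixture("calgary_giardia_2012")


@pytest.fixture(scope="session")
def calgary_reported(calgary):
    """The same dataset in its legacy reported-concentration form."""
    return mc.to_reported(calgary.records)


@pytest.fixture(scope="session")
def calgary_fits(calgary):
    """All five approach fits on the packaged dataset (computed once)."""
    return mc.fit_all_approaches(calgary.records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20181005)
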