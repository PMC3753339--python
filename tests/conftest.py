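import numpy as np
import pytest

from karyosim import GeneDistribution, RateParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["A", "B", "C", "unlinked"])
def distribution(request):
    return GeneDistribution.from_name(request.param)


@pytest.fixture
def default_rates():
    return RateParams()
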