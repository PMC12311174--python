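import numpy as np
import pytest

from fusemil.aggregator import AggregatorConfig, build_aggregator


@pytest.fixture(scope="session")
def tiny_agg_config():
    return AggregatorConfig(d_in=8, d_model=16, n_layers=2, n_heads=4,
                            d_ff=32, head_hidden=16, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_agg_config):
    return build_aggregator(tiny_agg_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
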