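import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import txconcord as tc


@pytest.fixture
def universe():
    return tc.GeneUniverse(genes=tuple(f"G{i:03d}" for i in range(1, 21)), label="toy")


@pytest.fixture
def rng():
    return random.Random(20210614)


def make_table(values, platform="short_read", sample="S", batch="b1", unit="RPKM"):
    return tc.ExpressionTable(
        platform=platform, sample=sample, batch=batch, unit=unit, values=dict(values)
    )


def make_set(genes, platform="short_read", sample="S", batch="b1", cutoff=0.0):
    return tc.DetectionSet(
        genes=frozenset(genes), platform=platform, sample=sample, batch=batch, cutoff=cutoff
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def set_factory():
    return make_set
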