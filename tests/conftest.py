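import numpy as np
import pytest

from somward import synthetic as syn
from somward import ingest
from somward.records import CategoryMap


@pytest.fixture(scope="session")
def demo_map() -> CategoryMap:
    return syn.demo_category_map()


@pytest.fixture(scope="session")
def small_population(demo_map):
    """A 4,000-record draw of the benchmark population plus coded records."""
    spec = syn.default_benchmark_spec(n_records=4000, seed=11)
    records, latent = syn.generate_population(spec)
    coded = [ingest.code_record(r, demo_map) for r in records]
    return records, latent, coded


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
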