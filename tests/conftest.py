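import numpy as np
import pytest
from hypothesis import settings

from lesionclass import benchmark, synthgen

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

#: master seed of the reference benchmark run
BENCH_SEED = 7


@pytest.fixture(scope="session")
def bench_data():
    """Reference benchmark splits: 150/class train, 50/class test, 64x64,
    segmented and featurised once per session."""
    return benchmark.prepare_data(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_classical(bench_data):
    return benchmark.classical_results(bench_data, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_cnn(bench_data):
    return benchmark.cnn_results(bench_data, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_retrieval(bench_data, bench_cnn):
    return benchmark.retrieval_results(bench_data, bench_cnn)


@pytest.fixture()
def benign_case():
    return synthgen.generate_case(synthgen.benign_preset(seed=11))


@pytest.fixture()
def malignant_case():
    return synthgen.generate_case(synthgen.malignant_preset(seed=11))
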