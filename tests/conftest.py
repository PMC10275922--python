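import pytest

from enoseslice import classification as cl
from enoseslice import preprocessing as pp
from enoseslice import windowing as wn
from enoseslice.synthetic import generate_dataset

BENCHMARK_SEED = 7
SPLIT_SEED = 3


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Default study-design benchmark: 100 records per class, fixed seed."""
    return generate_dataset(100, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_corrected(benchmark_dataset):
    return pp.baseline_correct_dataset(benchmark_dataset)


@pytest.fixture(scope="session")
def benchmark_w5_max(benchmark_corrected):
    """Max-statistic feature matrix at five windows for the benchmark."""
    scheme = wn.make_window_scheme(5)
    return wn.extract_features(benchmark_corrected, scheme, "max")


@pytest.fixture(scope="session")
def benchmark_split(benchmark_w5_max):
    return cl.split_train_test(benchmark_w5_max, seed=SPLIT_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    """Four records per class for fast structural tests."""
    return generate_dataset(4, seed=11)


@pytest.fixture(scope="session")
def small_corrected(small_dataset):
    return pp.baseline_correct_dataset(small_dataset)
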