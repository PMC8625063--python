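import numpy as np
import pytest

import shankpose as sp


@pytest.fixture(scope="session")
def small_benchmark():
    """2 subjects x 2 h of the default separable conditions (in memory)."""
    config = sp.default_config(duration_s=2 * 3600.0)
    return sp.make_benchmark(config, n_subjects=2, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_benchmark):
    """Featurized 15 s windows pooled over the small benchmark."""
    ds = sp.benchmark_datasets(small_benchmark, [15.0])[0]
    return sp.featurize_dataset(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_window(rng, n=300, fs=20.0, label="sitting"):
    """A labelled window of broadband Gaussian samples."""
    samples = rng.normal(0.0, 0.5, size=(n, 3)) + np.array([0.1, 0.0, 1.0])
    return sp.LabeledWindow(start=0.0, length=n / fs, label=label, samples=samples)
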