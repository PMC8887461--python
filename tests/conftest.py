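import numpy as np
import pytest

from rcacons import (
    DEFAULT_ADAPTOR,
    DEFAULT_REMNANT,
    ErrorModel,
    FilterConfig,
    SimParams,
    process_library,
    random_insert,
    simulate_reads,
)


@pytest.fixture
def filters():
    return FilterConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(n_reads, seed, *, error=None, classes=None, min_repeats=1,
                weights=(1.0,), insert_len=30, insert_seed=777, **kwargs):
    """Library parameters with one random insert per weight."""
    r = np.random.default_rng(insert_seed)
    inserts = [(random_insert(insert_len, r, f"ref{i}"), w) for i, w in enumerate(weights)]
    if error is not None:
        kwargs["error_model"] = ErrorModel(*error)
    if classes is not None:
        kwargs["class_fractions"] = classes
    return SimParams(inserts=inserts, n_reads=n_reads, seed=seed,
                     min_repeats=min_repeats, **kwargs)


@pytest.fixture(scope="session")
def zero_error_library():
    """60 error-free reads across all four artifact classes, with truth."""
    params = make_params(60, seed=9, error=(0.0, 0.0, 0.0))
    reads, truths = simulate_reads(params)
    return params, reads, truths


@pytest.fixture(scope="session")
def zero_error_records(zero_error_library):
    _, reads, _ = zero_error_library
    return process_library(reads, [DEFAULT_ADAPTOR], [DEFAULT_REMNANT], FilterConfig())


@pytest.fixture(scope="session")
def noisy_library():
    """150 reads at the default 10% error model, with truth."""
    params = make_params(150, seed=21)
    reads, truths = simulate_reads(params)
    return params, reads, truths
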