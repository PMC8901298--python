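"""Shared fixtures: phantoms at the sizes the different test tiers need."""

import numpy as np
import pytest

from glhosvd.phantom import add_rician_noise, default_phantom_spec, simulate_dwi
from glhosvd.tensor import DWIStack


def make_stack(intensities) -> DWIStack:
    """Wrap a raw H x W x Q array as a DWIStack with a trivial gradient table."""
    arr = np.asarray(intensities, dtype=np.float64)
    q = arr.shape[2]
    return DWIStack(arr, np.zeros(q), np.zeros((q, 3)))


@pytest.fixture(scope="session")
def phantom64():
    """Benchmark phantom: 64 x 64 slice, 12 directions + b=0, noise-free."""
    spec = default_phantom_spec(shape=(64, 64), n_directions=12, seed=7)
    clean, fa_truth, adc_truth = simulate_dwi(spec)
    return {"spec": spec, "clean": clean, "fa": fa_truth, "adc": adc_truth}


@pytest.fixture(scope="session")
def phantom16():
    """Small phantom for fast unit checks: 16 x 16, 12 directions + b=0."""
    spec = default_phantom_spec(shape=(16, 16), n_directions=12, seed=3)
    clean, fa_truth, adc_truth = simulate_dwi(spec)
    return {"spec": spec, "clean": clean, "fa": fa_truth, "adc": adc_truth}


@pytest.fixture(scope="session")
def noisy16(phantom16):
    """The small phantom with 5% Rician noise, fixed seed."""
    return add_rician_noise(phantom16["clean"], 0.05, seed=21)


@pytest.fixture(scope="session")
def noisy64(phantom64):
    """The benchmark phantom with 5% Rician noise, fixed seed."""
    return add_rician_noise(phantom64["clean"], 0.05, seed=21)
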