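"""Shared fixtures: the planted-edge benchmarks are expensive (a minute or
so each to simulate and featurize), so they are session-scoped and shared
between the recovery, evaluation and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from brainedge.benchmarks import benchmark_features

BENCH_SEED = 0


@pytest.fixture(scope="session")
def strong_benchmark():
    """61 channels, 280 trials, 20 planted edges, 0.3 vs 1.2 rad jitter."""
    return benchmark_features("strong", seed=BENCH_SEED)


@pytest.fixture(scope="session")
def weak_benchmark():
    """Same geometry in the low-contrast regime (0.9 vs 1.3 rad, more noise)."""
    return benchmark_features("weak", seed=BENCH_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
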