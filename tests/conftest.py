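import numpy as np
import pandas as pd
import pytest

from cnvmicro import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for end-to-end style tests."""
    return simulate_cohort(SimConfig(
        seed=11, n_individuals=60, n_snps=400, n_taxa=300, base_pool=150,
        dup_pool_bonus=60, library_size=5000))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def bh_stepup_oracle(p):
    """Definitional BH step-up: q_i = min over j with p_(j) >= p_(i) of
    min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, p[idx] * m / rank))
        q[idx] = running
    return q
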