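import numpy as np
import pytest

from pmdscape.caller import PmdCallConfig, call_pmds
from pmdscape.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small single-chromosome cohort shared across test modules."""
    cfg = SimConfig(chrom_sizes={"chr1": 6_000_000}, n_samples=5, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mini_calls(mini_cohort):
    """Called PMDs for the mini cohort (expensive; computed once)."""
    cfg = PmdCallConfig()
    return {s.sample_id: call_pmds(s, mini_cohort.layout, cfg)
            for s in mini_cohort.samples}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_coverage(intervals, length):
    """Per-bp occupancy oracle for a single chromosome."""
    cov = np.zeros(length, dtype=int)
    for s, e in intervals:
        cov[s:e] += 1
    return cov
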