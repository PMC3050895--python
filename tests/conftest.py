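import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from activeflora import refsim

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree():
    return refsim.build_taxonomy(5, 4)


@pytest.fixture(scope="session")
def refs(tree):
    return refsim.evolve_references(tree, seed=1)


@pytest.fixture(scope="session")
def small_reads(refs, tree):
    """Two samples x 1500 reads under the default mixture."""
    spec = refsim.CommunitySpec(n_samples=2, reads_per_sample=1500, seed=11)
    return refsim.simulate_reads(spec, refs, tree)


@pytest.fixture(scope="session")
def ssu_reads(refs, tree):
    """Pure-SSU reads for classifier tests (one sample, 1200 reads)."""
    spec = refsim.CommunitySpec(
        n_samples=1, reads_per_sample=1200, seed=13,
        class_mixture={"SSU": 1.0, "LSU": 0.0, "mRNA": 0.0, "sRNA": 0.0})
    return refsim.simulate_reads(spec, refs, tree)["A"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
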