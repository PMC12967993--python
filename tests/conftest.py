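import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from igloci.io_formats import RunConfig
from igloci.synthetic_locus import LocusBlueprint, assemble_locus

settings.register_profile(
    "suite", max_examples=25, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def point_mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for p in np.flatnonzero(rng.random(len(out)) < rate):
        p = int(p)
        alts = "ACGT".replace(out[p], "")
        out[p] = alts[rng.integers(3)]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_locus():
    """A mixed locus exercising every feature kind, shared across tests."""
    blueprint = LocusBlueprint(n_v_functional=7, n_v_pseudo=3, n_d=2,
                               n_jc_clusters=3, j_per_cluster=3,
                               orphon_count=1, switch_regions=True,
                               rng_seed=5)
    genome, truth = assemble_locus(blueprint)
    return blueprint, genome, truth
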