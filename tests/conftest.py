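import numpy as np
import pytest

from spudcoex import ParamSet, SimConfig, generate
from spudcoex.pipeline import analyze

#: Small but complete study: all planted roles present, three platforms.
SMALL_CFG = SimConfig(
    n_genes=150, n_chromosomes=3,
    n_tissue_specific_leaf=6, n_tissue_specific_tuber=6,
    n_ramp_genes=6, module_size=8, seed=11,
)


@pytest.fixture(scope="session")
def params() -> ParamSet:
    return ParamSet()


@pytest.fixture(scope="session")
def small_sim():
    return generate(SMALL_CFG)


@pytest.fixture(scope="session")
def small_analysis(small_sim, params):
    """Full analysis with query selection driven by the data."""
    return analyze(small_sim, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
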