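import numpy as np
import pytest

from calvease.pedigree import PedigreeTable, build_pedigree
from calvease.simulate import SimConfig, default_comparison_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_ped() -> PedigreeTable:
    """Sire, dam, and their offspring."""
    return build_pedigree(["s", "d", "o"], ["0", "0", "s"], ["0", "0", "d"])


def random_pedigree(rng, n: int, p_known: float = 0.7) -> PedigreeTable:
    """Random valid pedigree: each animal may draw parents among its elders."""
    sire, dam = ["0"], ["0"]
    for i in range(1, n):
        s = str(rng.integers(0, i)) if rng.random() < p_known and i > 1 else "0"
        d = str(rng.integers(0, i)) if rng.random() < p_known and i > 1 else "0"
        if s == d:
            d = "0"
        sire.append(s)
        dam.append(d)
    return build_pedigree([str(i) for i in range(n)], sire, dam)


SMALL_CFG = SimConfig(
    n_service_sires=40,
    n_mgs=30,
    n_dams=1500,
    records_per_sire=50,
    n_founder_males=100,
    n_founder_females=400,
    n_snp=200,
    n_herds=20,
)


@pytest.fixture(scope="session")
def small_scenario():
    """A 2,000-record scenario shared by solver and pipeline tests."""
    return default_comparison_scenario(7, cfg=SMALL_CFG)
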