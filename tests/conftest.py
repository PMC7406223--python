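import numpy as np
import pytest

from ecfcoev.simulate import (
    SimulationConfig,
    default_coupled_pairs,
    evolve_paired_alignment,
)


@pytest.fixture(scope="session")
def small_paired_alignment():
    """A small coupled simulation shared by fast tests (50 taxa, 2 planted pairs)."""
    cfg = SimulationConfig(
        n_taxa=50, len_ecf=20, len_asdi=15, coupled_pairs=((3, 5), (10, 2)), seed=7
    )
    return evolve_paired_alignment(cfg)


@pytest.fixture(scope="session")
def planted_dca_run():
    """The planted-contact study condition: M=2000, N=100, 8 pairs, rho=0.9."""
    base = SimulationConfig(n_taxa=2000, len_ecf=60, len_asdi=40, seed=11)
    pairs = default_coupled_pairs(base, 8)
    cfg = SimulationConfig(
        n_taxa=2000,
        len_ecf=60,
        len_asdi=40,
        coupled_pairs=pairs,
        coupling_prob=0.9,
        seed=11,
    )
    return evolve_paired_alignment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
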