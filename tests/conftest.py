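import numpy as np
import pytest

from congeal.sim_core import PopulationState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def build_state(haplotypes, positions, s_coef, neutral, favored=None,
                m=0.01, n_chromosomes=4, chrom_length=0.5):
    """Hand-built PopulationState for unit tests.

    ``haplotypes`` is (2N, S); individuals are split evenly into two demes
    in row order.
    """
    H = np.asarray(haplotypes, dtype=np.uint8)
    n = H.shape[0] // 2
    params = SimulationParams(s_mean=1.0, m=m, N_total=n,
                              n_chromosomes=n_chromosomes,
                              chrom_length_morgans=chrom_length)
    state = PopulationState(params)
    state.haplotypes = H
    state.positions = np.asarray(positions, dtype=float)
    state.s_coef = np.asarray(s_coef, dtype=float)
    state.neutral = np.asarray(neutral, dtype=bool)
    if favored is None:
        favored = np.ones(H.shape[1], dtype=np.int8)
    state.favored = np.asarray(favored, dtype=np.int8)
    return state
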