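import numpy as np
import pytest

from chromemu import lattice, params
from chromemu import _kernels as K


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(width, height, padding="none"):
    """Bare lattice (all unbound RBP) for hand-built configurations."""
    return lattice.SimulationState(width, height, padding)


def set_chromatin(state, positions, active=False, chain=-1):
    """Place chromatin sites by hand (no chain bookkeeping unless asked)."""
    for pos in positions:
        i = state._flat(pos)
        state.kind[i] = K.KIND_CHROM
        state.active[i] = 1 if active else 0
    state.refresh_code()


def set_rna(state, pos, n):
    state.rna[state._flat(pos)] = n
    state.refresh_code()


@pytest.fixture
def microphase_small():
    """Small microphase-like lattice for dynamics tests."""
    cfg = params.ScenarioConfig(
        name="microphase", width=20, height=20, box=5, chain_length=5,
        n_chains=16, padding="rna_rbp", chain_switching=False,
    )
    return lattice.build_scenario(cfg)
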