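import numpy as np
import pytest

from cortexsim import ModelParams
from cortexsim.engine import init_state, run


@pytest.fixture
def small_params():
    """A fast, fully featured world: 3 batches of 24 agents on a width-8 lattice."""
    return ModelParams(width=8, iz_height=12, batch_size=24, n_batches=3,
                       max_steps=50_000, seed=7)


@pytest.fixture
def small_run(small_params):
    return run(small_params)


@pytest.fixture
def small_state(small_params):
    return init_state(small_params)


def assert_invariants(state):
    """Exclusion, CP fullness, conservation and bookkeeping consistency."""
    p = state.params
    # exclusion in the IZ: occupied sites hold distinct agents
    iz_ids = state.iz[state.iz >= 0]
    assert len(iz_ids) == len(set(iz_ids.tolist()))
    # CP is always completely full up to cp_height
    cp = state.cp_view()
    assert (cp >= 0).all()
    assert len(set(cp.ravel().tolist())) == cp.size
    # conservation: introduced = IZ + queue + CP
    n_iz = int((state.comp == 1).sum())
    n_q = int((state.comp == 2).sum())
    n_cp = int((state.comp == 3).sum())
    assert state.n_introduced == n_iz + n_q + n_cp
    assert n_q == state.queue_length
    assert n_cp == cp.size == state.cp_height * p.width
    # position bookkeeping agrees with the grids
    for aid in iz_ids:
        assert state.iz[state.arow[aid], state.acol[aid]] == aid
    rows, cols = np.divmod(np.arange(cp.size), p.width)
    assert (state.arow[cp.ravel()] == rows).all()
    assert (state.acol[cp.ravel()] == cols).all()
    # active count matches
    assert state.n_active == int(state.active[: state.n_introduced].sum())
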