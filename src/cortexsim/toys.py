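"""Deterministic micro-worlds for tests and quick experiments.

These bypass the introduction schedule and build small, fully specified
states directly, keeping every engine invariant (conservation, exclusion,
CP fullness) intact.
"""
from __future__ import annotations

import numpy as np

from . import _kernels as K
from .engine import SimState, init_state
from .params import ModelParams


def _prefill_cp(state: SimState, n_rows: int) -> None:
    """Place all agents of a fresh state as passive CP rows (batch order,

    row-major from Layer 1 down, columns left to right)."""
    p = state.params
    w = p.width
    for aid in range(p.n_agents):
        r, c = divmod(aid, w)
        state.cp[r, c] = aid
        state.batch[aid] = aid // p.batch_size + 1
        state.active[aid] = 0
        state.comp[aid] = K.COMP_CP
        state.arow[aid] = r
        state.acol[aid] = c
    state.meta[K.M_CPH] = n_rows
    state.meta[K.M_INTRO] = p.n_agents
    state.meta[K.M_CURB] = p.n_batches + 1
    state.meta[K.M_NACT] = 0


def walker_cp(seed: int = 0, size: int = 5, **overrides) -> SimState:
    """A single active agent in the center of a passive-filled CP.

    The canonical single-walker oracle world: the lone active agent
    performs a biased random walk by swapping with its passive neighbors.
    """
    params = ModelParams(width=size, iz_height=4, batch_size=size * size,
                         n_batches=1, seed=seed, **overrides)
    state = init_state(params)
    _prefill_cp(state, size)
    center = (size // 2) * size + size // 2
    state.active[center] = 1
    state.meta[K.M_NACT] = 1
    return state


def all_active_cp(seed: int = 0, size: int = 4, **overrides) -> SimState:
    """A CP block in which every agent is still active (no passive anywhere).

    Used for the conversion-rule nucleation checks: under the local rule,
    only Layer-1 adjacency can seed the first conversion here.
    """
    params = ModelParams(width=size, iz_height=4, batch_size=size * size,
                         n_batches=1, seed=seed, **overrides)
    state = init_state(params)
    _prefill_cp(state, size)
    state.active[:] = 1
    state.meta[K.M_NACT] = params.n_agents
    return state


def iz_queue_world(seed: int = 0, **overrides) -> SimState:
    """A width-4 IZ holding 8 agents in its top two rows, empty CP.

    Two full-row crossings away from growing the CP by two rows; exercises
    the queue and row-insertion machinery.
    """
    params = ModelParams(width=4, iz_height=6, batch_size=8, n_batches=1,
                         seed=seed, **overrides)
    state = init_state(params)
    h = params.iz_height
    for aid in range(8):
        r = h - 1 - aid // 4
        c = aid % 4
        state.iz[r, c] = aid
        state.batch[aid] = 1
        state.active[aid] = 1
        state.comp[aid] = K.COMP_IZ
        state.arow[aid] = r
        state.acol[aid] = c
    state.meta[K.M_INTRO] = 8
    state.meta[K.M_CURB] = 2
    state.meta[K.M_NACT] = 8
    return state


def make_toy_scenarios(seed: int = 0) -> dict:
    """All packaged micro-worlds, rebuilt identically for a given seed."""
    return {
        "walker_cp": walker_cp(seed),
        "all_active_cp": all_active_cp(seed),
        "iz_queue": iz_queue_world(seed),
    }
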