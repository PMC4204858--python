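"""Direction sampling and move execution for the four CP movement hypotheses.

The four hypotheses for how Reelin shapes migration inside the cortical
plate are expressed as a signed vertical bias felt by an active agent:

* rule ``a`` -- no preferred vertical direction (Reelin plays no role),
* rule ``b`` -- a spatially uniform upward bias (global chemoattractant),
* rule ``c`` -- upward bias only within ``sensing_distance`` rows of
  Layer 1 (local attractant),
* rule ``d`` -- downward bias within the sensing band (local repellant).

In the IZ a constant upward bias ``rho_iz`` applies regardless of rule.
Exclusion aborts moves onto occupied IZ sites; in the always-full CP an
occupied target swaps the two agents instead (the only way a passive agent
can still be displaced).
"""
from __future__ import annotations

import numpy as np

from . import _kernels as K
from .engine import SimState, insert_cp_row
from .params import ConfigurationError
from .scenarios import GenotypeProfile

_DIR_CODE = {"up": K.UP, "down": K.DOWN, "left": K.LEFT, "right": K.RIGHT}
_DIR_NAME = {v: k for k, v in _DIR_CODE.items()}
_RULE_CODE = {"a": K.RULE_A, "b": K.RULE_B, "c": K.RULE_C, "d": K.RULE_D}


def effective_bias(rule: str, profile: GenotypeProfile, distance_to_layer1: int,
                   *, rho_cp: float, sensing_distance: int) -> float:
    """Signed CP bias in [-1, 1] for an agent at the given distance from Layer 1.

    Rule ``a`` is always unbiased; rules ``b``-``d`` return zero when the
    genotype removes chemotaxis (*reeler*).  Distance is the agent's own
    top-anchored row index, 1 = adjacent to Layer 1.
    """
    if rule not in _RULE_CODE:
        raise ConfigurationError(f"movement_rule: unknown rule {rule!r}")
    if distance_to_layer1 < 1:
        raise ValueError("distance_to_layer1 must be >= 1")
    return float(K.effective_bias(_RULE_CODE[rule], profile.chemotaxis_on,
                                  rho_cp, sensing_distance, distance_to_layer1))


def draw_direction(bias: float, p_vertical: float, rng: np.random.Generator) -> str:
    """Sample a move direction.

    Vertical attempt with probability ``p_vertical``, split
    up : down = (1 + bias)/2 : (1 - bias)/2; horizontal attempts split
    left/right equally.  The four probabilities sum to one.
    """
    if not -1.0 <= bias <= 1.0:
        raise ValueError(f"bias must lie in [-1, 1], got {bias}")
    return _DIR_NAME[int(K.draw_direction(bias, p_vertical, rng))]


def direction_probabilities(bias: float, p_vertical: float) -> dict[str, float]:
    """Exact law of :func:`draw_direction` (up, down, left, right)."""
    return {"up": p_vertical * 0.5 * (1.0 + bias),
            "down": p_vertical * 0.5 * (1.0 - bias),
            "left": (1.0 - p_vertical) * 0.5,
            "right": (1.0 - p_vertical) * 0.5}


def attempt_move_iz(state: SimState, agent_id: int, direction: str) -> SimState:
    """Execute one IZ movement attempt (exclusion: occupied targets abort).

    Up from the top row exits the agent into the crossing queue; if that
    completes a full row the row is inserted into the CP immediately.
    """
    if state.comp[agent_id] != K.COMP_IZ:
        raise ValueError(f"agent {agent_id} is not in the IZ")
    exited = K.attempt_move_iz(state.iz, state.arow, state.acol, state.comp,
                               state.queue, state.meta, state.ip,
                               agent_id, _DIR_CODE[direction])
    if exited:
        while state.queue_length >= state.params.width:
            insert_cp_row(state)
    return state


def attempt_move_cp(state: SimState, agent_id: int, direction: str) -> SimState:
    """Execute one CP movement attempt (occupied targets swap positions).

    Moves into Layer 1, from the CP back into the IZ, and lateral
    off-lattice moves are aborted.
    """
    if state.comp[agent_id] != K.COMP_CP:
        raise ValueError(f"agent {agent_id} is not in the CP")
    if not state.active[agent_id]:
        raise ValueError(f"agent {agent_id} is passive and cannot initiate a move")
    K.attempt_move_cp(state.cp, state.arow, state.acol, state.meta, state.ip,
                      agent_id, _DIR_CODE[direction])
    return state
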