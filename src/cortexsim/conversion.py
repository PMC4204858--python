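"""The four active-to-passive conversion hypotheses.

Conversion fixes a migrating neuron into its layer; it can happen only in
the cortical plate.  The hypotheses differ in what licenses an offer:

* rule ``i``  -- global: probability ``p_convert`` everywhere,
* rule ``ii`` -- local: probability ``p_convert`` only when the agent
  senses a passive agent in its Moore neighborhood (or touches Layer 1,
  whose resident cells count as passive-equivalent contacts -- this is how
  the first layer nucleates),
* rule ``iii`` -- Reelin stop signal: probability one on Layer-1 contact,
  nothing elsewhere; inert in genotypes that cannot receive Reelin,
* rule ``iv`` -- stop signal combined with local sensing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .engine import SimState
from .params import ConfigurationError


@dataclass(frozen=True)
class NeighborhoodReport:
    """Moore-neighborhood summary for one active CP agent."""

    n_passive_neighbors: int  # 0..8, over the 4 nearest + 4 next-nearest sites
    adjacent_to_layer1: bool  # agent sits in CP row 1


def sense_neighborhood(state: SimState, agent_id: int) -> NeighborhoodReport:
    """Exact passive count among occupied Moore sites, plus Layer-1 adjacency."""
    if state.comp[agent_id] != K.COMP_CP:
        raise ValueError(f"agent {agent_id} is not in the CP")
    n, adj = K.sense_neighborhood(state.cp, state.active, state.meta, state.ip,
                                  int(state.arow[agent_id]), int(state.acol[agent_id]))
    return NeighborhoodReport(n_passive_neighbors=int(n), adjacent_to_layer1=bool(adj))


def offer_conversion(state: SimState, agent_id: int,
                     rng: np.random.Generator | None = None) -> bool:
    """Offer one conversion under the state's (genotype-gated) rule.

    Returns True if the agent converted.  The conversion takes effect
    immediately, so later offers in the same phase sense it.
    """
    if state.comp[agent_id] != K.COMP_CP:
        raise ValueError(f"agent {agent_id} is not in the CP")
    if not state.active[agent_id]:
        raise ValueError(f"agent {agent_id} is already passive")
    if rng is None:
        rng = state.rng
    return bool(K.offer_conversion(state.cp, state.active, state.arow, state.acol,
                                   state.meta, state.ip, state.fp, agent_id, rng))
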