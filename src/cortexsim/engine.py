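"""World state and the per-step update algorithm.

The world has two lattices of shared width: a fixed intermediate zone (IZ)
that agents enter from the germinal boundary, and a cortical plate (CP)
that grows downward from Layer 1 one full row at a time as agents cross
over.  Each step runs four phases in order: introduce new agents into the
bottom IZ row, a movement sweep over IZ agents, a movement sweep over
active CP agents, and a conversion sweep over active CP agents.  The run
completes when the last active agent has converted to the passive state.

Row conventions (0-based in storage, 1-based in documentation):

* IZ: row 0 is the germinal boundary, row ``iz_height - 1`` is adjacent to
  the CP side.
* CP: row 0 is adjacent to Layer 1; new rows are inserted at index
  ``cp_height``, so an agent's row index is its distance from Layer 1 and
  never changes when the plate grows beneath it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .params import ModelParams
from .scenarios import ResolvedParams, apply_genotype

_STATUS_NAMES = {K.RUNNING: "running", K.COMPLETE: "complete",
                 K.NON_TERMINATED: "non_terminated"}
_MRULE_CODE = {"a": K.RULE_A, "b": K.RULE_B, "c": K.RULE_C, "d": K.RULE_D}
_CRULE_CODE = {"i": K.CONV_I, "ii": K.CONV_II, "iii": K.CONV_III, "iv": K.CONV_IV}


class SimulationError(RuntimeError):
    pass


@dataclass
class SimState:
    """The evolving world: grids, per-agent bookkeeping, queue, counters."""

    params: ResolvedParams
    iz: np.ndarray        # (iz_height, width) int32, -1 empty
    cp: np.ndarray        # (cp_rows_final, width) int32, rows [0, cp_height) valid
    batch: np.ndarray     # (n_agents,) int32, 1-based batch label
    active: np.ndarray    # (n_agents,) uint8
    comp: np.ndarray      # (n_agents,) uint8 compartment code
    arow: np.ndarray      # (n_agents,) int32 row in own grid, -1 if none
    acol: np.ndarray      # (n_agents,) int32
    queue: np.ndarray     # (n_agents,) int32 FIFO storage
    meta: np.ndarray      # (META_SIZE,) int64 counters, see _kernels
    ip: np.ndarray        # int64 kernel parameters
    fp: np.ndarray        # float64 kernel parameters
    p_move_b: np.ndarray  # (n_batches + 1,) float64 motility by batch
    rho_iz_b: np.ndarray  # (n_batches + 1,) float64 IZ bias by batch
    roster: np.ndarray    # (n_agents,) int32 scratch for phase rosters
    rng: np.random.Generator

    # -- readable views -------------------------------------------------
    @property
    def step_count(self) -> int:
        return int(self.meta[K.M_STEP])

    @property
    def cp_height(self) -> int:
        return int(self.meta[K.M_CPH])

    @property
    def n_introduced(self) -> int:
        return int(self.meta[K.M_INTRO])

    @property
    def current_batch(self) -> int:
        return int(self.meta[K.M_CURB])

    @property
    def status(self) -> str:
        return _STATUS_NAMES[int(self.meta[K.M_STATUS])]

    @property
    def queue_length(self) -> int:
        return int(self.meta[K.M_QTAIL] - self.meta[K.M_QHEAD])

    @property
    def queue_ids(self) -> np.ndarray:
        """Waiting agents in FIFO order (oldest first)."""
        return self.queue[int(self.meta[K.M_QHEAD]):int(self.meta[K.M_QTAIL])].copy()

    @property
    def n_active(self) -> int:
        return int(self.meta[K.M_NACT])

    def cp_view(self) -> np.ndarray:
        """The occupied CP block, row 0 adjacent to Layer 1."""
        return self.cp[: self.cp_height]

    def _kernel_args(self):
        return (self.iz, self.cp, self.batch, self.active, self.comp,
                self.arow, self.acol, self.queue, self.meta,
                self.ip, self.fp, self.p_move_b, self.rho_iz_b,
                self.roster, self.rng)


@dataclass
class CompletedSim:
    """Final state plus the provenance needed to reproduce the run."""

    state: SimState
    seed: int
    steps: int
    status: str

    @property
    def params(self) -> ResolvedParams:
        return self.state.params


def init_state(params) -> SimState:
    """Build the empty world for a validated parameter set.

    Accepts a :class:`ModelParams` (the genotype is resolved here) or an
    already-resolved parameter set.
    """
    rp = apply_genotype(params)
    p = rp.base
    n = p.n_agents
    iz = np.full((p.iz_height, p.width), -1, np.int32)
    cp = np.full((p.cp_rows_final, p.width), -1, np.int32)
    meta = np.zeros(K.META_SIZE, np.int64)
    meta[K.M_CURB] = 1
    ip = np.zeros(K.IP_SIZE, np.int64)
    ip[K.IP_WIDTH] = p.width
    ip[K.IP_IZH] = p.iz_height
    ip[K.IP_BATCH] = p.batch_size
    ip[K.IP_NBATCH] = p.n_batches
    ip[K.IP_MRULE] = _MRULE_CODE[p.movement_rule]
    ip[K.IP_CRULE] = _CRULE_CODE[p.conversion_rule]
    ip[K.IP_SENSE] = p.sensing_distance
    ip[K.IP_MAXSTEP] = p.max_steps
    ip[K.IP_CHEMO] = 1 if rp.profile.chemotaxis_on else 0
    ip[K.IP_STOP] = 1 if rp.profile.stop_signal_on else 0
    ip[K.IP_PERIODIC] = 1 if p.periodic_boundaries else 0
    fp = np.zeros(K.FP_SIZE, np.float64)
    fp[K.FP_PVERT] = p.p_vertical
    fp[K.FP_RHOIZ] = rp.profile.rho_iz_effective
    fp[K.FP_RHOCP] = p.rho_cp
    fp[K.FP_PCONV] = p.p_convert
    return SimState(
        params=rp, iz=iz, cp=cp,
        batch=np.zeros(n, np.int32),
        active=np.zeros(n, np.uint8),
        comp=np.zeros(n, np.uint8),
        arow=np.full(n, -1, np.int32),
        acol=np.full(n, -1, np.int32),
        queue=np.full(n, -1, np.int32),
        meta=meta, ip=ip, fp=fp,
        p_move_b=rp.p_move_by_batch.astype(np.float64),
        rho_iz_b=rp.rho_iz_by_batch.astype(np.float64),
        roster=np.zeros(n, np.int32),
        rng=np.random.default_rng(p.seed),
    )


def _require_running(state: SimState) -> None:
    if state.status != "running":
        raise SimulationError(f"state is {state.status}, not running")


def fill_iz_bottom_row(state: SimState) -> SimState:
    """Introduce current-batch agents into empty sites of the bottom IZ row."""
    _require_running(state)
    K.fill_iz_bottom_row(state.iz, state.batch, state.active, state.comp,
                         state.arow, state.acol, state.meta, state.ip)
    return state


def exit_iz_to_queue(state: SimState, agent_id: int) -> SimState:
    """Move an agent from the IZ top row into the FIFO crossing queue.

    Engine contract: whenever the queue reaches a full row, the row is
    inserted into the CP immediately.
    """
    if state.comp[agent_id] != K.COMP_IZ or state.arow[agent_id] != state.params.iz_height - 1:
        raise SimulationError(f"agent {agent_id} is not in the IZ top row")
    K.attempt_move_iz(state.iz, state.arow, state.acol, state.comp,
                      state.queue, state.meta, state.ip, agent_id, K.UP)
    while state.queue_length >= state.params.width:
        insert_cp_row(state)
    return state


def insert_cp_row(state: SimState) -> SimState:
    """Dequeue one full row of agents into a new bottom CP row."""
    if state.queue_length < state.params.width:
        raise SimulationError(
            f"queue holds {state.queue_length} agents; a full row needs "
            f"{state.params.width}")
    K.insert_cp_row(state.cp, state.arow, state.acol, state.comp,
                    state.queue, state.meta, state.ip, state.rng)
    return state


def step(state: SimState) -> SimState:
    """Advance the world by one full time step (all four phases)."""
    _require_running(state)
    K.step_once(*state._kernel_args())
    return state


def run(params) -> CompletedSim:
    """Iterate steps until the run completes or hits the step cap."""
    state = init_state(params)
    K.run_loop(*state._kernel_args())
    return CompletedSim(state=state, seed=state.params.seed,
                        steps=state.step_count, status=state.status)
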