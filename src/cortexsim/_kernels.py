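"""Compiled inner loops of the lattice engine.

All state lives in flat numpy arrays so the per-step update (a random
sequential exclusion-process sweep) can run in nopython mode.  The Python
modules :mod:`cortexsim.engine`, :mod:`cortexsim.movement` and
:mod:`cortexsim.conversion` are thin wrappers over these kernels; there is
exactly one implementation of every rule.

Randomness is drawn from a single ``np.random.Generator`` threaded through
every kernel, so a (params, seed) pair fixes the trajectory bit-for-bit.
RNG consumption order is part of the repository contract:

* a direction draw consumes exactly two uniforms,
* motility thinning consumes one uniform only when the agent's p_move < 1,
* a conversion offer consumes one uniform only when the rule gives the
  agent a non-degenerate conversion probability (rule iii and the stop
  part of rule iv are deterministic and consume none),
* inserting a CP row consumes ``width - 1`` bounded integers
  (Fisher-Yates column permutation).
"""
import numpy as np
from numba import njit

# direction codes
UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
# compartment codes
COMP_UNBORN, COMP_IZ, COMP_QUEUE, COMP_CP = 0, 1, 2, 3
# run status codes
RUNNING, COMPLETE, NON_TERMINATED = 0, 1, 2
# movement rule codes (a-d) and conversion rule codes (i-iv)
RULE_A, RULE_B, RULE_C, RULE_D = 0, 1, 2, 3
CONV_I, CONV_II, CONV_III, CONV_IV = 0, 1, 2, 3

# meta vector layout
M_STEP, M_CPH, M_INTRO, M_CURB, M_QHEAD, M_QTAIL, M_STATUS, M_NACT = range(8)
META_SIZE = 8

# integer parameter vector layout
(IP_WIDTH, IP_IZH, IP_BATCH, IP_NBATCH, IP_MRULE, IP_CRULE, IP_SENSE,
 IP_MAXSTEP, IP_CHEMO, IP_STOP, IP_PERIODIC) = range(11)
IP_SIZE = 11

# float parameter vector layout
FP_PVERT, FP_RHOIZ, FP_RHOCP, FP_PCONV = range(4)
FP_SIZE = 4


@njit(cache=True)
def draw_direction(bias, p_vertical, rng):
    """Sample one of up/down/left/right.

    Vertical with probability ``p_vertical``, split up:(1+bias)/2,
    down:(1-bias)/2; horizontal splits left/right equally.
    """
    if rng.random() < p_vertical:
        if rng.random() < 0.5 * (1.0 + bias):
            return UP
        return DOWN
    if rng.random() < 0.5:
        return LEFT
    return RIGHT


@njit(cache=True)
def effective_bias(mrule, chemo_on, rho_cp, sensing_distance, distance):
    """Signed CP bias for an agent ``distance`` rows from Layer 1 (>= 1)."""
    if mrule == RULE_A or not chemo_on:
        return 0.0
    if mrule == RULE_B:
        return rho_cp
    if distance <= sensing_distance:
        if mrule == RULE_C:
            return rho_cp
        return -rho_cp  # RULE_D
    return 0.0


@njit(cache=True)
def attempt_move_iz(iz, arow, acol, comp, queue, meta, ip, aid, direction):
    """One movement attempt for an IZ agent.  Returns 1 if it exited to the queue.

    Exclusion: a move onto an occupied site is aborted.  Down from row 0
    (germinal boundary) and lateral off-lattice moves are aborted (lateral
    wraps when periodic boundaries are enabled).  Up from the top row
    removes the agent from the lattice into the FIFO crossing queue.
    """
    w = ip[IP_WIDTH]
    h = ip[IP_IZH]
    r = arow[aid]
    c = acol[aid]
    if direction == UP:
        if r == h - 1:
            iz[r, c] = -1
            comp[aid] = COMP_QUEUE
            arow[aid] = -1
            acol[aid] = -1
            queue[meta[M_QTAIL]] = aid
            meta[M_QTAIL] += 1
            return 1
        if iz[r + 1, c] == -1:
            iz[r, c] = -1
            iz[r + 1, c] = aid
            arow[aid] = r + 1
    elif direction == DOWN:
        if r > 0 and iz[r - 1, c] == -1:
            iz[r, c] = -1
            iz[r - 1, c] = aid
            arow[aid] = r - 1
    else:
        if direction == LEFT:
            c2 = c - 1
        else:
            c2 = c + 1
        if c2 < 0 or c2 >= w:
            if ip[IP_PERIODIC] == 1:
                c2 = c2 % w
            else:
                return 0
        if iz[r, c2] == -1:
            iz[r, c] = -1
            iz[r, c2] = aid
            acol[aid] = c2
    return 0


@njit(cache=True)
def insert_cp_row(cp, arow, acol, comp, queue, meta, ip, rng):
    """Move the ``width`` oldest queue entries into a new full bottom CP row.

    Columns are assigned by a seeded Fisher-Yates permutation.  Under the
    top-anchored row convention the new row takes index ``cp_height`` and
    existing agents keep their distance from Layer 1, which realizes the
    one-row upward displacement of the previously layered region.
    """
    w = ip[IP_WIDTH]
    row = meta[M_CPH]
    colperm = np.empty(w, np.int64)
    for i in range(w):
        colperm[i] = i
    for i in range(w - 1, 0, -1):
        j = rng.integers(0, i + 1)
        t = colperm[i]
        colperm[i] = colperm[j]
        colperm[j] = t
    base = meta[M_QHEAD]
    for k in range(w):
        aid = queue[base + k]
        c = colperm[k]
        cp[row, c] = aid
        comp[aid] = COMP_CP
        arow[aid] = row
        acol[aid] = c
    meta[M_QHEAD] += w
    meta[M_CPH] += 1


@njit(cache=True)
def attempt_move_cp(cp, arow, acol, meta, ip, aid, direction):
    """One movement attempt for an active CP agent.

    Up from row 0 (into Layer 1) and down from the bottom CP row (into the
    IZ) are aborted; lateral off-lattice moves abort unless periodic.  An
    occupied target swaps the two agents; an empty target (cannot occur in
    a full CP, kept for engine generality) is a plain relocation.
    """
    w = ip[IP_WIDTH]
    cph = meta[M_CPH]
    r = arow[aid]
    c = acol[aid]
    if direction == UP:
        if r == 0:
            return
        r2, c2 = r - 1, c
    elif direction == DOWN:
        if r == cph - 1:
            return
        r2, c2 = r + 1, c
    else:
        if direction == LEFT:
            c2 = c - 1
        else:
            c2 = c + 1
        if c2 < 0 or c2 >= w:
            if ip[IP_PERIODIC] == 1:
                c2 = c2 % w
            else:
                return
        r2 = r
    other = cp[r2, c2]
    if other == -1:
        cp[r, c] = -1
        cp[r2, c2] = aid
    else:
        cp[r, c] = other
        cp[r2, c2] = aid
        arow[other] = r
        acol[other] = c
    arow[aid] = r2
    acol[aid] = c2


@njit(cache=True)
def sense_neighborhood(cp, active, meta, ip, r, c):
    """Count passive agents in the Moore neighborhood of CP site (r, c).

    Returns ``(n_passive, adjacent_to_layer1)``.  Off-lattice lateral sites
    contribute nothing (unless periodic); sites above row 0 belong to
    Layer 1 and are reported through the adjacency flag rather than the
    count.
    """
    w = ip[IP_WIDTH]
    cph = meta[M_CPH]
    n = 0
    for dr in range(-1, 2):
        rr = r + dr
        if rr < 0 or rr >= cph:
            continue
        for dc in range(-1, 2):
            if dr == 0 and dc == 0:
                continue
            cc = c + dc
            if cc < 0 or cc >= w:
                if ip[IP_PERIODIC] == 1:
                    cc = cc % w
                else:
                    continue
            t = cp[rr, cc]
            if t >= 0 and active[t] == 0:
                n += 1
    return n, r == 0


@njit(cache=True)
def offer_conversion(cp, active, arow, acol, meta, ip, fp, aid, rng):
    """Offer one active CP agent the chance to convert.  Returns 1 on conversion.

    Rule i: convert with probability p_convert unconditionally.
    Rule ii: convert with probability p_convert iff at least one Moore
        neighbor is passive or the agent is adjacent to Layer 1 (resident
        Layer-1 cells count as passive-equivalent contacts).
    Rule iii: convert with probability one iff adjacent to Layer 1; the
        stop signal is Reelin-dependent and is disabled for genotypes that
        cannot receive it, in which case rule iii can never fire.
    Rule iv: the rule-iii stop check first, then rule ii; with the stop
        signal disabled it degrades exactly to rule ii.
    """
    crule = ip[IP_CRULE]
    r = arow[aid]
    if crule == CONV_III:
        if ip[IP_STOP] == 1 and r == 0:
            active[aid] = 0
            meta[M_NACT] -= 1
            return 1
        return 0
    if crule == CONV_IV and ip[IP_STOP] == 1 and r == 0:
        active[aid] = 0
        meta[M_NACT] -= 1
        return 1
    if crule == CONV_I:
        if rng.random() < fp[FP_PCONV]:
            active[aid] = 0
            meta[M_NACT] -= 1
            return 1
        return 0
    # CONV_II, or the local part of CONV_IV
    n_passive, adj = sense_neighborhood(cp, active, meta, ip, r, c=acol[aid])
    if adj or n_passive > 0:
        if rng.random() < fp[FP_PCONV]:
            active[aid] = 0
            meta[M_NACT] -= 1
            return 1
    return 0


@njit(cache=True)
def fill_iz_bottom_row(iz, batch, active, comp, arow, acol, meta, ip):
    """Introduce agents of the current batch into empty sites of IZ row 0.

    Stops at the batch quota; when the quota is exhausted the batch counter
    advances so the next step begins introducing the next batch.
    """
    nb = ip[IP_NBATCH]
    bs = ip[IP_BATCH]
    w = ip[IP_WIDTH]
    cb = meta[M_CURB]
    if cb > nb:
        return
    rem = cb * bs - meta[M_INTRO]
    for c in range(w):
        if rem == 0:
            break
        if iz[0, c] == -1:
            aid = meta[M_INTRO]
            iz[0, c] = aid
            batch[aid] = cb
            active[aid] = 1
            comp[aid] = COMP_IZ
            arow[aid] = 0
            acol[aid] = c
            meta[M_INTRO] += 1
            meta[M_NACT] += 1
            rem -= 1
    if rem == 0:
        meta[M_CURB] = cb + 1


@njit(cache=True)
def movement_phase_iz(iz, cp, batch, active, comp, arow, acol, queue, meta,
                      ip, fp, p_move_b, rho_iz_b, roster, rng):
    """N_IZ draws with replacement from the phase-start IZ roster.

    A drawn agent that has already left the IZ consumes its draw with no
    action.  Whenever an exit brings the queue to a full row, the row is
    inserted immediately (re-checking, so multiple rows can insert)."""
    n = 0
    for aid in range(meta[M_INTRO]):
        if comp[aid] == COMP_IZ:
            roster[n] = aid
            n += 1
    for _ in range(n):
        aid = roster[rng.integers(0, n)]
        if comp[aid] != COMP_IZ:
            continue
        pm = p_move_b[batch[aid]]
        if pm < 1.0 and rng.random() >= pm:
            continue
        d = draw_direction(rho_iz_b[batch[aid]], fp[FP_PVERT], rng)
        exited = attempt_move_iz(iz, arow, acol, comp, queue, meta, ip, aid, d)
        if exited == 1:
            while meta[M_QTAIL] - meta[M_QHEAD] >= ip[IP_WIDTH]:
                insert_cp_row(cp, arow, acol, comp, queue, meta, ip, rng)


@njit(cache=True)
def movement_phase_cp(cp, batch, active, comp, arow, acol, meta,
                      ip, fp, p_move_b, roster, rng):
    """N_CP draws with replacement from the phase-start active-CP roster."""
    n = 0
    for aid in range(meta[M_INTRO]):
        if comp[aid] == COMP_CP and active[aid] == 1:
            roster[n] = aid
            n += 1
    for _ in range(n):
        aid = roster[rng.integers(0, n)]
        pm = p_move_b[batch[aid]]
        if pm < 1.0 and rng.random() >= pm:
            continue
        bias = effective_bias(ip[IP_MRULE], ip[IP_CHEMO] == 1, fp[FP_RHOCP],
                              ip[IP_SENSE], arow[aid] + 1)
        d = draw_direction(bias, fp[FP_PVERT], rng)
        attempt_move_cp(cp, arow, acol, meta, ip, aid, d)


@njit(cache=True)
def conversion_phase(cp, batch, active, comp, arow, acol, meta,
                     ip, fp, roster, rng):
    """N_CP conversion offers, drawn with replacement from the phase-start roster.

    Conversions take effect immediately: later draws in the same phase
    sense the newly passive agent, and a draw landing on an agent that has
    already converted is consumed with no action."""
    n = 0
    for aid in range(meta[M_INTRO]):
        if comp[aid] == COMP_CP and active[aid] == 1:
            roster[n] = aid
            n += 1
    for _ in range(n):
        aid = roster[rng.integers(0, n)]
        if active[aid] == 0:
            continue
        offer_conversion(cp, active, arow, acol, meta, ip, fp, aid, rng)


@njit(cache=True)
def step_once(iz, cp, batch, active, comp, arow, acol, queue, meta,
              ip, fp, p_move_b, rho_iz_b, roster, rng):
    """One full time step: fill, IZ movement, CP movement, conversion.

    Afterwards the step counter advances; the run completes when every
    introduced agent is passive (which implies the IZ and queue are empty),
    and is flagged non-terminated once the step cap is reached."""
    fill_iz_bottom_row(iz, batch, active, comp, arow, acol, meta, ip)
    movement_phase_iz(iz, cp, batch, active, comp, arow, acol, queue, meta,
                      ip, fp, p_move_b, rho_iz_b, roster, rng)
    movement_phase_cp(cp, batch, active, comp, arow, acol, meta,
                      ip, fp, p_move_b, roster, rng)
    conversion_phase(cp, batch, active, comp, arow, acol, meta,
                     ip, fp, roster, rng)
    meta[M_STEP] += 1
    if meta[M_INTRO] == ip[IP_BATCH] * ip[IP_NBATCH] and meta[M_NACT] == 0:
        meta[M_STATUS] = COMPLETE
    elif meta[M_STEP] >= ip[IP_MAXSTEP]:
        meta[M_STATUS] = NON_TERMINATED


@njit(cache=True)
def run_loop(iz, cp, batch, active, comp, arow, acol, queue, meta,
             ip, fp, p_move_b, rho_iz_b, roster, rng):
    while meta[M_STATUS] == RUNNING:
        step_once(iz, cp, batch, active, comp, arow, acol, queue, meta,
                  ip, fp, p_move_b, rho_iz_b, roster, rng)
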