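"""Numba kernels for the discrete-time group-structured loop.

The kernel mirrors, draw-scheme for draw-scheme, the reference step built from
:mod:`mlscoop.intragroup` and :mod:`mlscoop.group_events`: per step (1) one
uniform variate per below-threshold group partitioned into A-birth / B-birth /
nothing, (2) at most one split among threshold groups with independent uniform
allocation, (3) at most one death via a single categorical draw over the mode's
per-group probabilities.  It exists because the rare-death (Moran-limit) and
phase-diagram experiments need tens of millions of steps; the two engines are
cross-validated statistically in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fitness modes
MODE_NEUTRAL, MODE_RELATIVE, MODE_ABSOLUTE = 0, 1, 2
MODE_CODES = {"neutral": MODE_NEUTRAL, "relative": MODE_RELATIVE,
              "absolute": MODE_ABSOLUTE}

# event bit flags recorded per step
EV_SPLIT, EV_DEATH, EV_ABORT = 1, 2, 4

# terminal statuses
ST_TIMEOUT, ST_EXTINCT, ST_A_FIXED, ST_B_FIXED = 0, 1, 2, 3
STATUS_NAMES = {ST_TIMEOUT: "timeout", ST_EXTINCT: "extinct",
                ST_A_FIXED: "a_fixed", ST_B_FIXED: "b_fixed"}


@njit(cache=True)
def run_lattice(nA0, nB0, K, b, mu, a, Kg, mode, T, seed,
                record_every, stop_on_homog, death_first):
    """Advance a population for up to T steps.

    Returns (nA, nB, t_end, status, records) where records rows are
    (t, Ng, n_allA, n_allB, sum_nA, sum_nB, event_flags); row 0 is the initial
    state and the final state is always recorded.
    """
    np.random.seed(seed)
    cap = Kg + 1
    nA = np.zeros(cap, np.int64)
    nB = np.zeros(cap, np.int64)
    ng = nA0.shape[0]
    for j in range(ng):
        nA[j] = nA0[j]
        nB[j] = nB0[j]
    probs = np.zeros(cap, np.float64)

    n_rec = 2 + (T // record_every if record_every > 0 else 0)
    rec = np.zeros((n_rec, 7), np.int64)
    ri = 0

    # initial snapshot
    allA = 0
    allB = 0
    sA = 0
    sB = 0
    for j in range(ng):
        sA += nA[j]
        sB += nB[j]
        if nB[j] == 0:
            allA += 1
        elif nA[j] == 0:
            allB += 1
    rec[ri, 0] = 0
    rec[ri, 1] = ng
    rec[ri, 2] = allA
    rec[ri, 3] = allB
    rec[ri, 4] = sA
    rec[ri, 5] = sB
    ri += 1

    status = ST_TIMEOUT
    t = 0
    for t in range(1, T + 1):
        ev = 0
        if death_first and ng > 0 and mu > 0.0:
            died = _death(nA, nB, probs, ng, mu, a, mode)
            if died >= 0:
                ng -= 1
                nA[died] = nA[ng]
                nB[died] = nB[ng]
                ev |= EV_DEATH
        if ng > 0:
            # parallel within-group reproduction
            for j in range(ng):
                n = nA[j] + nB[j]
                if n < K:
                    free = (K - n) / K
                    pA = (nA[j] / K) * free
                    pB = b * (nB[j] / K) * free
                    u = np.random.random()
                    if u < pA:
                        nA[j] += 1
                    elif u < pA + pB:
                        nB[j] += 1
            # one splitting event if eligible
            if ng < Kg:
                nthr = 0
                for j in range(ng):
                    if nA[j] + nB[j] == K:
                        nthr += 1
                if nthr > 0:
                    pick = np.random.randint(0, nthr)
                    idx = -1
                    c = 0
                    for j in range(ng):
                        if nA[j] + nB[j] == K:
                            if c == pick:
                                idx = j
                                break
                            c += 1
                    mA = np.random.randint(0, nA[idx] + 1)
                    mB = np.random.randint(0, nB[idx] + 1)
                    if (mA == 0 and mB == 0) or (mA == nA[idx] and mB == nB[idx]):
                        ev |= EV_ABORT
                    else:
                        nA[ng] = nA[idx] - mA
                        nB[ng] = nB[idx] - mB
                        nA[idx] = mA
                        nB[idx] = mB
                        ng += 1
                        ev |= EV_SPLIT
            # one death draw on the post-split population
            if (not death_first) and mu > 0.0:
                died = _death(nA, nB, probs, ng, mu, a, mode)
                if died >= 0:
                    ng -= 1
                    nA[died] = nA[ng]
                    nB[died] = nB[ng]
                    ev |= EV_DEATH

        allA = 0
        allB = 0
        sA = 0
        sB = 0
        for j in range(ng):
            sA += nA[j]
            sB += nB[j]
            if nB[j] == 0:
                allA += 1
            elif nA[j] == 0:
                allB += 1
        done = False
        if ng == 0:
            status = ST_EXTINCT
            done = True
        elif stop_on_homog:
            if sB == 0:
                status = ST_A_FIXED
                done = True
            elif sA == 0:
                status = ST_B_FIXED
                done = True
        if done or t == T or (record_every > 0 and t % record_every == 0):
            rec[ri, 0] = t
            rec[ri, 1] = ng
            rec[ri, 2] = allA
            rec[ri, 3] = allB
            rec[ri, 4] = sA
            rec[ri, 5] = sB
            rec[ri, 6] = ev
            ri += 1
        if done:
            break

    return nA[:ng].copy(), nB[:ng].copy(), t, status, rec[:ri].copy()


@njit(cache=True)
def _death(nA, nB, probs, ng, mu, a, mode):
    """Single categorical death draw; returns victim index or -1."""
    if ng == 0:
        return -1
    if mode == MODE_NEUTRAL:
        for j in range(ng):
            probs[j] = mu / ng
    elif mode == MODE_RELATIVE:
        W = 0.0
        for j in range(ng):
            f = nA[j] / (nA[j] + nB[j])
            probs[j] = 1.0 - a * f
            W += probs[j]
        if W <= 0.0:
            for j in range(ng):
                probs[j] = mu / ng
        else:
            for j in range(ng):
                probs[j] = mu * probs[j] / W
    else:
        for j in range(ng):
            f = nA[j] / (nA[j] + nB[j])
            probs[j] = (mu / ng) * (1.0 - a * f)
    u = np.random.random()
    acc = 0.0
    for j in range(ng):
        acc += probs[j]
        if u < acc:
            return j
    return -1


@njit(cache=True)
def mc_reach_threshold(n0, K, b, delta, reps, seed):
    """Monte-Carlo absorption frequency of a single group with per-step
    survival probability delta: fraction of runs reaching K from size n0."""
    np.random.seed(seed)
    hits = 0
    for _ in range(reps):
        n = n0
        while True:
            if np.random.random() >= delta:
                break  # eliminated
            free = (K - n) / K
            p_up = b * (n / K) * free
            if np.random.random() < p_up:
                n += 1
                if n == K:
                    hits += 1
                    break
    return hits / reps
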