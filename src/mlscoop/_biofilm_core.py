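"""Numba kernel for the off-lattice biofilm model.

One step = motion (pairwise + substrate pseudo-forces, blended with a random
unit vector), division (per-phenotype Poisson with logistic suppression),
predation-interface detection (topmost cell per substrate window) and removal
(Poisson over the interface).  The kernel mutates preallocated state arrays in
place and is driven by the protocol wrappers in :mod:`mlscoop.biofilm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# terminal statuses
BF_TIMEOUT, BF_EXTINCT, BF_SUCCESS, BF_ASOCIAL_FIXED = 0, 1, 2, 3
# stop modes
STOP_NONE, STOP_SEEDING, STOP_FIXATION = 0, 1, 2


@njit(cache=True)
def _accumulate_forces(pos, G, n, anchors, H, G_sub, forces):
    """Net pseudo-force on every active cell (pairwise + substrate anchors).

    Pair magnitude H/d^6 - ((G_i + G_j)/2)/d^2 along the separation axis
    (positive = repulsive); anchors use G_sub/2 as the attraction constant.
    """
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 1e-18:
                d2 = 1e-18
            d = np.sqrt(d2)
            coef = (H / (d2 * d2 * d2) - 0.5 * (G[i] + G[j]) / d2) / d
            fx = coef * dx
            fy = coef * dy
            fz = coef * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    na = anchors.shape[0]
    half_gs = 0.5 * G_sub
    for i in range(n):
        for k in range(na):
            dx = pos[i, 0] - anchors[k, 0]
            dy = pos[i, 1] - anchors[k, 1]
            dz = pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 1e-18:
                d2 = 1e-18
            d = np.sqrt(d2)
            coef = (H / (d2 * d2 * d2) - half_gs / d2) / d
            forces[i, 0] += coef * dx
            forces[i, 1] += coef * dy
            forces[i, 2] += coef * dz


@njit(cache=True)
def _interface(pos, n, pad, bins, D, win_best, win_of):
    """Mark the topmost cell of each occupied substrate window; returns the
    interface size.  ``win_best[w]`` holds the winning cell index."""
    nwin = bins * bins
    for w in range(nwin):
        win_best[w] = -1
    for i in range(n):
        ix = int(np.floor(pos[i, 0] / D)) + pad
        iy = int(np.floor(pos[i, 1] / D)) + pad
        if ix < 0:
            ix = 0
        elif ix >= bins:
            ix = bins - 1
        if iy < 0:
            iy = 0
        elif iy >= bins:
            iy = bins - 1
        w = ix * bins + iy
        win_of[i] = w
        if win_best[w] < 0 or pos[i, 2] > pos[win_best[w], 2]:
            win_best[w] = i
    m = 0
    for w in range(nwin):
        if win_best[w] >= 0:
            m += 1
    return m


@njit(cache=True)
def run_biofilm(pos, G, soc, n, steps, seed,
                anchors, H, G_sub, F, r_soc, r_asoc, K_BF, dt, L,
                speed, jitter, div_jitter, pad, bins, D,
                do_random, do_division, do_removal,
                stop_mode, stop_n,
                record_every, rec):
    """Advance the biofilm for up to ``steps`` steps, mutating state in place.

    Returns (n, status, steps_done, rows_recorded, interface_step_sum) where
    ``interface_step_sum`` accumulates the per-step interface size (for
    exposure statistics).  ``rec`` rows are (t, n_social, n_asocial, m).
    """
    np.random.seed(seed)
    cap = pos.shape[0]
    forces = np.zeros((cap, 3))
    win_best = np.full(bins * bins, -1, np.int64)
    win_of = np.zeros(cap, np.int64)
    scratch = np.zeros(cap, np.int64)
    status = BF_TIMEOUT
    ri = 0
    m_sum = 0.0
    t = 0
    for t in range(1, steps + 1):
        # --- motion ---
        _accumulate_forces(pos, G, n, anchors, H, G_sub, forces)
        for i in range(n):
            fx, fy, fz = forces[i, 0], forces[i, 1], forces[i, 2]
            fn = np.sqrt(fx * fx + fy * fy + fz * fz)
            if do_random:
                # random unit vector via normalised gaussian triple
                rx = np.random.normal()
                ry = np.random.normal()
                rz = np.random.normal()
                rn = np.sqrt(rx * rx + ry * ry + rz * rz)
                if rn < 1e-12:
                    rx, ry, rz, rn = 1.0, 0.0, 0.0, 1.0
                rx /= rn
                ry /= rn
                rz /= rn
                if fn > 0.0:
                    ux = (1.0 - F) * fx / fn + F * rx
                    uy = (1.0 - F) * fy / fn + F * ry
                    uz = (1.0 - F) * fz / fn + F * rz
                else:
                    ux, uy, uz = rx, ry, rz
            else:
                if fn == 0.0:
                    continue
                ux, uy, uz = fx / fn, fy / fn, fz / fn
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            if un < 1e-12:
                continue
            pos[i, 0] += speed * ux / un
            pos[i, 1] += speed * uy / un
            pos[i, 2] += speed * uz / un
            if pos[i, 2] < 0.0:
                pos[i, 2] = -pos[i, 2]  # reflective substrate
            # uniqueness jitter
            pos[i, 0] += jitter * (2.0 * np.random.random() - 1.0)
            pos[i, 1] += jitter * (2.0 * np.random.random() - 1.0)
            pos[i, 2] += jitter * (2.0 * np.random.random() - 1.0)
            if pos[i, 2] < 0.0:
                pos[i, 2] = -pos[i, 2]

        # --- division ---
        if do_division and n > 0:
            for phen in range(2):  # 0 = asocial, 1 = social
                cnt = 0
                for i in range(n):
                    if soc[i] == phen:
                        cnt += 1
                if cnt == 0:
                    continue
                r = r_soc if phen == 1 else r_asoc
                lam = cnt * r * (1.0 - n / K_BF) * dt
                if lam <= 0.0:
                    continue
                k = np.random.poisson(lam)
                if k > cnt:
                    k = cnt
                if k > cap - n:
                    k = cap - n
                done = 0
                attempts = 0
                while done < k and attempts < 1000 * k:
                    j = np.random.randint(0, n)
                    attempts += 1
                    if soc[j] != phen:
                        continue
                    dup = False
                    for q in range(done):
                        if scratch[q] == j:
                            dup = True
                            break
                    if dup:
                        continue
                    scratch[done] = j
                    done += 1
                for q in range(done):
                    j = scratch[q]
                    pos[n, 0] = pos[j, 0] + div_jitter * (2.0 * np.random.random() - 1.0)
                    pos[n, 1] = pos[j, 1] + div_jitter * (2.0 * np.random.random() - 1.0)
                    pos[n, 2] = pos[j, 2] + div_jitter * (2.0 * np.random.random() - 1.0)
                    if pos[n, 2] < 0.0:
                        pos[n, 2] = -pos[n, 2]
                    G[n] = G[j]
                    soc[n] = soc[j]
                    n += 1

        # --- predation interface + removal ---
        m = _interface(pos, n, pad, bins, D, win_best, win_of)
        m_sum += m
        if do_removal and m > 0:
            k = np.random.poisson(m * L * dt)
            if k > m:
                k = m
            if k > 0:
                # collect interface cell indices
                cnt = 0
                for w in range(bins * bins):
                    if win_best[w] >= 0:
                        scratch[cnt] = win_best[w]
                        cnt += 1
                # partial Fisher-Yates: pick k distinct victims
                for q in range(k):
                    pick = q + np.random.randint(0, cnt - q)
                    tmp = scratch[q]
                    scratch[q] = scratch[pick]
                    scratch[pick] = tmp
                # remove victims (descending index order keeps swaps valid)
                victims = np.sort(scratch[:k])[::-1]
                for q in range(k):
                    v = victims[q]
                    n -= 1
                    pos[v, 0] = pos[n, 0]
                    pos[v, 1] = pos[n, 1]
                    pos[v, 2] = pos[n, 2]
                    G[v] = G[n]
                    soc[v] = soc[n]

        n_soc = 0
        for i in range(n):
            if soc[i] == 1:
                n_soc += 1

        done_run = False
        if n == 0:
            status = BF_EXTINCT
            done_run = True
        elif stop_mode == STOP_SEEDING and n > stop_n:
            status = BF_SUCCESS
            done_run = True
        elif stop_mode == STOP_FIXATION:
            if n_soc == n:
                status = BF_SUCCESS
                done_run = True
            elif n_soc == 0:
                status = BF_ASOCIAL_FIXED
                done_run = True
        if (record_every > 0 and t % record_every == 0) or done_run or t == steps:
            if ri < rec.shape[0]:
                rec[ri, 0] = t
                rec[ri, 1] = n_soc
                rec[ri, 2] = n - n_soc
                rec[ri, 3] = m
                ri += 1
        if done_run:
            break
    return n, status, t, ri, m_sum
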