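"""Numba event loop for the continuous-time lattice dynamics.

The simulation is an exact (source-centric) Gillespie scheme: every occupied
site carries independent exponential clocks for extinction (delta),
destruction (e), a colonization attempt (beta for NC, 1 for the exploiter)
and -- for NC -- a construction attempt (c); vacant sites carry only the
destruction clock and destroyed sites carry nothing.  An attempt picks a
uniform offset of the relevant neighborhood and fires only if the target is
eligible (vacant for colonization, destroyed for construction); ineligible
targets are null events.  Summed over sources this reproduces the
target-centric rates exactly: a vacant site is colonized at
``beta * n_NC(Z*) / |Z*|`` and a destroyed site renewed at
``c * n_NC(Z) / |Z|``.

State codes follow :class:`nichesim.lattice.CellState`:
-1 destroyed, 0 vacant, 1 NC, 2 exploiter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event-count indices
EV_DEATH_NC = 0
EV_DEATH_EX = 1
EV_DESTROY_OCC = 2
EV_DESTROY_VAC = 3
EV_COL_NC = 4
EV_COL_EX = 5
EV_CONSTRUCT = 6
EV_NULL = 7
N_EVENT_TYPES = 8


@njit(cache=True)
def _list_add(lst, pos, n, s):
    lst[n] = s
    pos[s] = n
    return n + 1


@njit(cache=True)
def _list_remove(lst, pos, n, s):
    i = pos[s]
    n -= 1
    last = lst[n]
    lst[i] = last
    pos[last] = i
    pos[s] = -1
    return n


@njit(cache=True)
def _wrap_target(s, off_i, off_j, L):
    i = s // L
    j = s - i * L
    ni = (i + off_i) % L
    nj = (j + off_j) % L
    return ni * L + nj


@njit(cache=True)
def _max_chebyshev(lst_nc, n_nc, lst_ex, n_ex, L, ci, cj):
    best = 0
    for k in range(n_nc + n_ex):
        s = lst_nc[k] if k < n_nc else lst_ex[k - n_nc]
        i = s // L
        j = s - i * L
        di = abs(i - ci)
        if L - di < di:
            di = L - di
        dj = abs(j - cj)
        if L - dj < dj:
            dj = L - dj
        d = di if di > dj else dj
        if d > best:
            best = d
    return best


@njit(cache=True)
def run_kernel(
    state,  # int8 (L*L,) flat, modified in place
    L,
    delta,
    e,
    c,
    beta,
    col_off,  # (k*, 2) int64
    con_off,  # (k, 2) int64
    global_con,  # bool
    t_max,
    sample_dt,
    seed,
    row_idx,  # transect row to record each sample, -1 disables
    snap_stride,  # full-grid snapshot every snap_stride samples, 0 disables
    track_extent,  # bool: record max Chebyshev radius of occupied sites
    center_i,
    center_j,
):
    np.random.seed(seed)
    N = L * L
    n_samples = int(np.floor(t_max / sample_dt + 1e-9)) + 1
    times = np.empty(n_samples, dtype=np.float64)
    for k in range(n_samples):
        times[k] = k * sample_dt
    fracs = np.zeros((n_samples, 4), dtype=np.float64)  # p-, p0, p+, p++
    extent = np.zeros(n_samples, dtype=np.int32)
    if row_idx >= 0:
        rows = np.zeros((n_samples, L), dtype=np.int8)
    else:
        rows = np.zeros((1, 1), dtype=np.int8)
    if snap_stride > 0:
        n_snaps = (n_samples + snap_stride - 1) // snap_stride
        snaps = np.zeros((n_snaps, N), dtype=np.int8)
    else:
        snaps = np.zeros((1, 1), dtype=np.int8)

    # site lists with positional index for O(1) swap-remove
    nc_list = np.empty(N, dtype=np.int32)
    ex_list = np.empty(N, dtype=np.int32)
    vac_list = np.empty(N, dtype=np.int32)
    nc_pos = np.full(N, -1, dtype=np.int32)
    ex_pos = np.full(N, -1, dtype=np.int32)
    vac_pos = np.full(N, -1, dtype=np.int32)
    n_nc = 0
    n_ex = 0
    n_vac = 0
    for s in range(N):
        if state[s] == 1:
            n_nc = _list_add(nc_list, nc_pos, n_nc, s)
        elif state[s] == 2:
            n_ex = _list_add(ex_list, ex_pos, n_ex, s)
        elif state[s] == 0:
            n_vac = _list_add(vac_list, vac_pos, n_vac, s)

    k_col = len(col_off)
    k_con = len(con_off)
    R_nc = delta + e + beta + c
    R_ex = delta + e + 1.0
    counts = np.zeros(N_EVENT_TYPES, dtype=np.int64)
    occ_time = 0.0  # integral of occupied-site count over time
    absorbed_at = -1.0

    t = 0.0
    si = 0  # next sample index
    while True:
        B = n_nc * R_nc + n_ex * R_ex + n_vac * e
        if n_nc + n_ex == 0 and absorbed_at < 0.0:
            absorbed_at = t
        if B <= 0.0:
            # frozen configuration: fill remaining samples and stop
            while si < n_samples:
                fracs[si, 1] = n_vac / N
                fracs[si, 2] = n_nc / N
                fracs[si, 3] = n_ex / N
                fracs[si, 0] = 1.0 - fracs[si, 1] - fracs[si, 2] - fracs[si, 3]
                if track_extent:
                    extent[si] = _max_chebyshev(
                        nc_list, n_nc, ex_list, n_ex, L, center_i, center_j
                    )
                if row_idx >= 0:
                    for jj in range(L):
                        rows[si, jj] = state[row_idx * L + jj]
                if snap_stride > 0 and si % snap_stride == 0:
                    for ss in range(N):
                        snaps[si // snap_stride, ss] = state[ss]
                si += 1
            t = t_max
            break
        dt = np.random.exponential(1.0 / B)
        t_new = t + dt
        horizon = t_new if t_new < t_max else t_max
        while si < n_samples and times[si] <= horizon + 1e-12:
            fracs[si, 1] = n_vac / N
            fracs[si, 2] = n_nc / N
            fracs[si, 3] = n_ex / N
            fracs[si, 0] = 1.0 - fracs[si, 1] - fracs[si, 2] - fracs[si, 3]
            if track_extent:
                extent[si] = _max_chebyshev(
                    nc_list, n_nc, ex_list, n_ex, L, center_i, center_j
                )
            if row_idx >= 0:
                for jj in range(L):
                    rows[si, jj] = state[row_idx * L + jj]
            if snap_stride > 0 and si % snap_stride == 0:
                for ss in range(N):
                    snaps[si // snap_stride, ss] = state[ss]
            si += 1
        occ_time += (horizon - t) * (n_nc + n_ex)
        if t_new > t_max:
            t = t_max
            break
        t = t_new

        u = np.random.random() * B
        if u < n_nc * R_nc:
            s = nc_list[np.random.randint(0, n_nc)]
            v = np.random.random() * R_nc
            if v < delta:
                state[s] = 0
                n_nc = _list_remove(nc_list, nc_pos, n_nc, s)
                n_vac = _list_add(vac_list, vac_pos, n_vac, s)
                counts[EV_DEATH_NC] += 1
            elif v < delta + e:
                state[s] = -1
                n_nc = _list_remove(nc_list, nc_pos, n_nc, s)
                counts[EV_DESTROY_OCC] += 1
            elif v < delta + e + beta:
                o = np.random.randint(0, k_col)
                tgt = _wrap_target(s, col_off[o, 0], col_off[o, 1], L)
                if state[tgt] == 0:
                    state[tgt] = 1
                    n_vac = _list_remove(vac_list, vac_pos, n_vac, tgt)
                    n_nc = _list_add(nc_list, nc_pos, n_nc, tgt)
                    counts[EV_COL_NC] += 1
                else:
                    counts[EV_NULL] += 1
            else:
                if global_con:
                    tgt = np.random.randint(0, N)
                else:
                    o = np.random.randint(0, k_con)
                    tgt = _wrap_target(s, con_off[o, 0], con_off[o, 1], L)
                if state[tgt] == -1:
                    state[tgt] = 0
                    n_vac = _list_add(vac_list, vac_pos, n_vac, tgt)
                    counts[EV_CONSTRUCT] += 1
                else:
                    counts[EV_NULL] += 1
        elif u < n_nc * R_nc + n_ex * R_ex:
            s = ex_list[np.random.randint(0, n_ex)]
            v = np.random.random() * R_ex
            if v < delta:
                state[s] = 0
                n_ex = _list_remove(ex_list, ex_pos, n_ex, s)
                n_vac = _list_add(vac_list, vac_pos, n_vac, s)
                counts[EV_DEATH_EX] += 1
            elif v < delta + e:
                state[s] = -1
                n_ex = _list_remove(ex_list, ex_pos, n_ex, s)
                counts[EV_DESTROY_OCC] += 1
            else:
                o = np.random.randint(0, k_col)
                tgt = _wrap_target(s, col_off[o, 0], col_off[o, 1], L)
                if state[tgt] == 0:
                    state[tgt] = 2
                    n_vac = _list_remove(vac_list, vac_pos, n_vac, tgt)
                    n_ex = _list_add(ex_list, ex_pos, n_ex, tgt)
                    counts[EV_COL_EX] += 1
                else:
                    counts[EV_NULL] += 1
        else:
            s = vac_list[np.random.randint(0, n_vac)]
            state[s] = -1
            n_vac = _list_remove(vac_list, vac_pos, n_vac, s)
            counts[EV_DESTROY_VAC] += 1

    absorbed = (n_nc + n_ex) == 0
    return times, fracs, counts, occ_time, absorbed, absorbed_at, extent, rows, snaps
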