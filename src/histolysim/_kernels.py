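"""Numba-compiled inner loop of the particle simulation.

One call runs a block of synchronous Euler steps on structure-of-arrays
state.  Per step: turning draws, pairwise contact forces from pre-update
positions, confinement-wall forces, position update with the active
boundary wrap, then phagocytosis and bond-break state transitions on the
post-update positions.

Neighbor search uses a uniform cell grid in CSR layout (counting sort,
rebuilt once per step) whose cell size is at least the largest
small-particle interaction diameter.  Small-small pairs come from a half
neighborhood (self cell plus E, NW, N, NE) so each unordered pair is
visited exactly once; neighbor cell ids and their periodic image shifts
are precomputed per cell.  The few large fat body cells scan the grid
cells covering their interaction disk and pair with each other directly.

Kind codes: 0 muscle, 1 hemocyte, 2 fat.  Muscle state: 0 uneaten, 1 eaten.
Radius-zero particles (fat cells still in the depth) do not interact.
"""

import numpy as np
from numba import njit

KIND_MUSCLE = 0
KIND_HEMOCYTE = 1
KIND_FAT = 2
UNEATEN = 0
EATEN = 1

# half neighborhood: self, E, NW, N, NE; full 3x3 neighborhood
_HALF_OFF = ((0, 0), (1, 0), (-1, 1), (0, 1), (1, 1))
_FULL_OFF = ((-1, -1), (0, -1), (1, -1), (-1, 0), (0, 0), (1, 0),
             (-1, 1), (0, 1), (1, 1))


@njit(cache=True, inline="always")
def _adhesion(i, j, kind, state, host, a_HF, a_HH, a_FF, a_E):
    ki = kind[i]
    kj = kind[j]
    # phagocytosis adhesion: uneaten muscle with any hemocyte; eaten with host
    if ki == KIND_MUSCLE and kj == KIND_HEMOCYTE:
        if state[i] == UNEATEN or host[i] == j:
            return a_E
        return a_HH
    if kj == KIND_MUSCLE and ki == KIND_HEMOCYTE:
        if state[j] == UNEATEN or host[j] == i:
            return a_E
        return a_HH
    # eaten muscle units count as hemocytes for intercellular adhesion
    ei = ki
    if ki == KIND_MUSCLE:
        if state[i] != EATEN:
            return 0.0
        ei = KIND_HEMOCYTE
    ej = kj
    if kj == KIND_MUSCLE:
        if state[j] != EATEN:
            return 0.0
        ej = KIND_HEMOCYTE
    if ei == KIND_HEMOCYTE and ej == KIND_HEMOCYTE:
        return a_HH
    if ei == KIND_FAT and ej == KIND_FAT:
        return a_FF
    return a_HF


@njit(cache=True, inline="always")
def _accumulate(i, j, dx, dy, radius, kind, state, host, F,
                k, a_HF, a_HH, a_FF, a_E):
    """Add the contact force for pair (i, j) given the image-resolved
    center offset (dx, dy) from i to j."""
    rsum = radius[i] + radius[j]
    d2 = dx * dx + dy * dy
    if d2 >= rsum * rsum:
        return
    d = np.sqrt(d2)
    if d == 0.0:
        # coincident centers: fixed +x axis for the lower index; a carried
        # muscle unit concentric with its host is simply left at rest
        if (kind[i] == KIND_MUSCLE and host[i] == j) or \
           (kind[j] == KIND_MUSCLE and host[j] == i):
            return
        fmag = -k * rsum
        ex = 1.0 if i < j else -1.0
        F[i, 0] += fmag * ex
        F[j, 0] -= fmag * ex
        return
    aij = _adhesion(i, j, kind, state, host, a_HF, a_HH, a_FF, a_E)
    fmag = -k * (rsum - d) + aij
    ex = dx / d
    ey = dy / d
    F[i, 0] += fmag * ex
    F[i, 1] += fmag * ey
    F[j, 0] -= fmag * ex
    F[j, 1] -= fmag * ey


@njit(cache=True, inline="always")
def _pair_minimage(i, j, pos, radius, kind, state, host, F,
                   k, a_HF, a_HH, a_FF, a_E, L, walled):
    """Contact force with explicit minimum-image resolution."""
    dx = pos[j, 0] - pos[i, 0]
    if dx > 0.5 * L:
        dx -= L
    elif dx < -0.5 * L:
        dx += L
    dy = pos[j, 1] - pos[i, 1]
    if not walled:
        if dy > 0.5 * L:
            dy -= L
        elif dy < -0.5 * L:
            dy += L
    _accumulate(i, j, dx, dy, radius, kind, state, host, F,
                k, a_HF, a_HH, a_FF, a_E)


@njit(cache=True, inline="always")
def _cell_index(x, inv_cell, ncell):
    c = int(x * inv_cell)
    if c >= ncell:
        c = ncell - 1
    elif c < 0:
        c = 0
    return c


@njit(cache=True)
def _build_grid(pos, radius, kind, cell_of, start, order, ncell, inv_cell):
    """Counting-sort CSR grid over the small particles."""
    n = pos.shape[0]
    ncells = ncell * ncell
    for c in range(ncells + 1):
        start[c] = 0
    for i in range(n):
        if kind[i] == KIND_FAT or radius[i] <= 0.0:
            cell_of[i] = -1
            continue
        cx = _cell_index(pos[i, 0], inv_cell, ncell)
        cy = _cell_index(pos[i, 1], inv_cell, ncell)
        c = cy * ncell + cx
        cell_of[i] = c
        start[c + 1] += 1
    for c in range(ncells):
        start[c + 1] += start[c]
    for i in range(n):
        c = cell_of[i]
        if c >= 0:
            order[start[c]] = i
            start[c] += 1
    for c in range(ncells, 0, -1):
        start[c] = start[c - 1]
    start[0] = 0


@njit(cache=True)
def _neighbor_tables(ncell, L, walled, offsets):
    """Per-cell neighbor cell ids and image shifts; -1 marks a neighbor
    suppressed by the non-periodic (walled) y boundary."""
    m = len(offsets)
    ncells = ncell * ncell
    nbr = np.empty((ncells, m), dtype=np.int32)
    shx = np.zeros((ncells, m), dtype=np.float64)
    shy = np.zeros((ncells, m), dtype=np.float64)
    for cy in range(ncell):
        for cx in range(ncell):
            c = cy * ncell + cx
            for t in range(m):
                ox, oy = offsets[t]
                ccx = cx + ox
                sx = 0.0
                if ccx < 0:
                    ccx += ncell
                    sx = -L
                elif ccx >= ncell:
                    ccx -= ncell
                    sx = L
                ccy = cy + oy
                sy = 0.0
                if ccy < 0:
                    if walled:
                        nbr[c, t] = -1
                        continue
                    ccy += ncell
                    sy = -L
                elif ccy >= ncell:
                    if walled:
                        nbr[c, t] = -1
                        continue
                    ccy -= ncell
                    sy = L
                nbr[c, t] = ccy * ncell + ccx
                shx[c, t] = sx
                shy[c, t] = sy
    return nbr, shx, shy


@njit(cache=True)
def run_chunk(pos, heading, radius, kind, state, host, v, p_turn,
              mu, k, a_HF, a_HH, a_FF, a_E, dt, L,
              wall_w, walled, r_small, turn_u, turn_ang):
    """Advance the state in place by ``turn_u.shape[0]`` steps.

    Returns ``(code, particle, substep)``; code 0 on success, 1 if a
    position became non-finite.
    """
    n = pos.shape[0]
    n_sub = turn_u.shape[0]
    ncell = int(L / r_small)
    # the fat-disk cell scan must never wrap onto the same cell twice
    max_fat_r = 0.0
    n_fat = 0
    for i in range(n):
        if kind[i] == KIND_FAT:
            n_fat += 1
            if radius[i] > max_fat_r:
                max_fat_r = radius[i]
    if ncell > 0:
        max_span = int((max_fat_r + 0.5 * r_small) * ncell / L) + 1
    else:
        max_span = 1
    use_grid = ncell > 3 and ncell > 2 * max_span + 1
    if not use_grid:
        ncell = 1
    inv_cell = ncell / L
    ncells = ncell * ncell
    cell_of = np.empty(n, dtype=np.int32)
    start = np.empty(ncells + 1, dtype=np.int32)
    order = np.empty(n, dtype=np.int32)
    F = np.empty((n, 2), dtype=np.float64)
    coef = dt / mu
    fat_idx = np.empty(n_fat, dtype=np.int32)
    m = 0
    for i in range(n):
        if kind[i] == KIND_FAT:
            fat_idx[m] = i
            m += 1
    r_small_max = 0.5 * r_small
    nbr5, shx5, shy5 = _neighbor_tables(ncell, L, walled, _HALF_OFF)
    nbr9, shx9, shy9 = _neighbor_tables(ncell, L, walled, _FULL_OFF)
    n_uneaten = 0
    for i in range(n):
        if kind[i] == KIND_MUSCLE and state[i] == UNEATEN:
            n_uneaten += 1

    _build_grid(pos, radius, kind, cell_of, start, order, ncell, inv_cell)
    fresh = True

    for s in range(n_sub):
        if not fresh:
            _build_grid(pos, radius, kind, cell_of, start, order, ncell,
                        inv_cell)

        # 1) turning draws for motile particles
        for i in range(n):
            if v[i] > 0.0 and turn_u[s, i] < p_turn[i]:
                a = turn_ang[s, i]
                heading[i, 0] = np.cos(a)
                heading[i, 1] = np.sin(a)

        # 2) contact forces at pre-update positions
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
        if use_grid:
            for c0 in range(ncells):
                for idx0 in range(start[c0], start[c0 + 1]):
                    i = order[idx0]
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    for t in range(5):
                        c = nbr5[c0, t]
                        if c < 0:
                            continue
                        sx = shx5[c0, t]
                        sy = shy5[c0, t]
                        if t == 0:
                            for idx in range(idx0 + 1, start[c0 + 1]):
                                j = order[idx]
                                _accumulate(i, j, pos[j, 0] - xi,
                                            pos[j, 1] - yi, radius, kind,
                                            state, host, F, k, a_HF, a_HH,
                                            a_FF, a_E)
                        else:
                            for idx in range(start[c], start[c + 1]):
                                j = order[idx]
                                _accumulate(i, j, pos[j, 0] + sx - xi,
                                            pos[j, 1] + sy - yi, radius,
                                            kind, state, host, F, k, a_HF,
                                            a_HH, a_FF, a_E)
            # fat-small pairs: scan the grid cells covering each fat disk
            for fi in range(n_fat):
                f = fat_idx[fi]
                if radius[f] <= 0.0:
                    continue
                xf = pos[f, 0]
                yf = pos[f, 1]
                reach = radius[f] + r_small_max
                span = int(reach * inv_cell) + 1
                cx = _cell_index(xf, inv_cell, ncell)
                cy = _cell_index(yf, inv_cell, ncell)
                for oy in range(-span, span + 1):
                    ccy = cy + oy
                    sy = 0.0
                    if ccy < 0:
                        if walled:
                            continue
                        ccy += ncell
                        sy = -L
                    elif ccy >= ncell:
                        if walled:
                            continue
                        ccy -= ncell
                        sy = L
                    for ox in range(-span, span + 1):
                        ccx = cx + ox
                        sx = 0.0
                        if ccx < 0:
                            ccx += ncell
                            sx = -L
                        elif ccx >= ncell:
                            ccx -= ncell
                            sx = L
                        c = ccy * ncell + ccx
                        for idx in range(start[c], start[c + 1]):
                            j = order[idx]
                            _accumulate(f, j, pos[j, 0] + sx - xf,
                                        pos[j, 1] + sy - yf, radius, kind,
                                        state, host, F, k, a_HF, a_HH,
                                        a_FF, a_E)
        else:
            for i in range(n):
                if kind[i] == KIND_FAT:
                    continue
                for j in range(i + 1, n):
                    if kind[j] == KIND_FAT:
                        continue
                    _pair_minimage(i, j, pos, radius, kind, state, host,
                                   F, k, a_HF, a_HH, a_FF, a_E, L, walled)
            for fi in range(n_fat):
                f = fat_idx[fi]
                if radius[f] <= 0.0:
                    continue
                for j in range(n):
                    if j == f or kind[j] == KIND_FAT or radius[j] <= 0.0:
                        continue
                    _pair_minimage(f, j, pos, radius, kind, state, host, F,
                                   k, a_HF, a_HH, a_FF, a_E, L, walled)
        # fat-fat pairs: direct (few cells)
        for a_ in range(n_fat):
            f1 = fat_idx[a_]
            if radius[f1] <= 0.0:
                continue
            for b_ in range(a_ + 1, n_fat):
                f2 = fat_idx[b_]
                if radius[f2] <= 0.0:
                    continue
                _pair_minimage(f1, f2, pos, radius, kind, state, host, F,
                               k, a_HF, a_HH, a_FF, a_E, L, walled)

        # 3) confinement walls
        if walled and wall_w > 0.0:
            for i in range(n):
                if radius[i] <= 0.0 and kind[i] == KIND_FAT:
                    continue
                y = pos[i, 1]
                d_bot = y
                d_top = L - y
                if d_bot <= d_top:
                    ov = radius[i] + wall_w - d_bot
                    if ov > 0.0:
                        F[i, 1] += k * ov
                else:
                    ov = radius[i] + wall_w - d_top
                    if ov > 0.0:
                        F[i, 1] -= k * ov

        # 4) overdamped Euler update and boundary wrap
        for i in range(n):
            x = pos[i, 0] + coef * (v[i] * heading[i, 0] + F[i, 0])
            y = pos[i, 1] + coef * (v[i] * heading[i, 1] + F[i, 1])
            if not (np.isfinite(x) and np.isfinite(y)):
                return 1, i, s
            x = x % L
            if x < 0.0:
                x += L
            if not walled:
                y = y % L
                if y < 0.0:
                    y += L
            pos[i, 0] = x
            pos[i, 1] = y
        fresh = False

        # 5) phagocytosis: uneaten muscle overlapping a hemocyte is eaten by
        #    the nearest-center overlapping hemocyte (tie -> lowest index)
        if n_uneaten > 0:
            _build_grid(pos, radius, kind, cell_of, start, order, ncell,
                        inv_cell)
            fresh = True
            for i in range(n):
                if kind[i] != KIND_MUSCLE or state[i] != UNEATEN:
                    continue
                xi = pos[i, 0]
                yi = pos[i, 1]
                c0 = cell_of[i]
                best = -1
                best_d2 = 0.0
                for t in range(9):
                    c = nbr9[c0, t]
                    if c < 0:
                        continue
                    sx = shx9[c0, t]
                    sy = shy9[c0, t]
                    for idx in range(start[c], start[c + 1]):
                        j = order[idx]
                        if kind[j] == KIND_HEMOCYTE:
                            dx = pos[j, 0] + sx - xi
                            dy = pos[j, 1] + sy - yi
                            rsum = radius[i] + radius[j]
                            d2 = dx * dx + dy * dy
                            if d2 < rsum * rsum:
                                if best < 0 or d2 < best_d2 or \
                                   (d2 == best_d2 and j < best):
                                    best = j
                                    best_d2 = d2
                if best >= 0:
                    state[i] = EATEN
                    host[i] = best
                    n_uneaten -= 1

        # 6) bond break: eaten muscle that lost contact with its host reverts
        for i in range(n):
            if kind[i] != KIND_MUSCLE or state[i] != EATEN:
                continue
            h = host[i]
            dx = pos[h, 0] - pos[i, 0]
            if dx > 0.5 * L:
                dx -= L
            elif dx < -0.5 * L:
                dx += L
            dy = pos[h, 1] - pos[i, 1]
            if not walled:
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
            rsum = radius[i] + radius[h]
            if dx * dx + dy * dy >= rsum * rsum:
                state[i] = UNEATEN
                host[i] = -1
                n_uneaten += 1

    return 0, -1, -1
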