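"""Numba kernels for homotopic 3D thinning.

A voxel is *simple* when its removal changes neither the connectivity
of the foreground (26-connectivity) nor of the background
(6-connectivity, evaluated inside the 18-neighborhood): removing a
simple point preserves the topology of the object. The thinning driver
deletes simple points sequentially in increasing distance-transform
order, never touching anchor voxels; anchors are supplied by the caller
(ridge voxels of the Euclidean distance transform), which is what makes
the result a medial *surface* for plates and a medial *axis* for rods.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OFFS6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], np.int64)


@njit(cache=True)
def _patch27(fg, x, y, z):
    out = np.zeros((3, 3, 3), np.bool_)
    nx, ny, nz = fg.shape
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    out[dx + 1, dy + 1, dz + 1] = fg[xx, yy, zz]
    out[1, 1, 1] = False
    return out


@njit(cache=True)
def is_simple(patch):
    """Simple-point test on a 3x3x3 patch with the center removed."""
    # (1) foreground 26-neighbors form exactly one 26-component
    n = 0
    seed = -1
    for idx in range(27):
        i, j, k = idx // 9, (idx // 3) % 3, idx % 3
        if patch[i, j, k]:
            n += 1
            if seed < 0:
                seed = idx
    if n == 0:
        return False
    visited = np.zeros(27, np.bool_)
    stack = np.empty(27, np.int64)
    sp = 0
    stack[sp] = seed
    sp += 1
    visited[seed] = True
    cnt = 1
    while sp > 0:
        sp -= 1
        cur = stack[sp]
        ci, cj, ck = cur // 9, (cur // 3) % 3, cur % 3
        for di in range(-1, 2):
            for dj in range(-1, 2):
                for dk in range(-1, 2):
                    ii, jj, kk = ci + di, cj + dj, ck + dk
                    if 0 <= ii < 3 and 0 <= jj < 3 and 0 <= kk < 3:
                        idx2 = ii * 9 + jj * 3 + kk
                        if patch[ii, jj, kk] and not visited[idx2]:
                            visited[idx2] = True
                            cnt += 1
                            stack[sp] = idx2
                            sp += 1
    if cnt != n:
        return False
    # (2) background 6-neighbors of the center form one 6-component
    # within the 18-neighborhood
    bg6 = np.empty((6, 3), np.int64)
    nb6 = 0
    for m in range(6):
        i, j, k = 1 + _OFFS6[m, 0], 1 + _OFFS6[m, 1], 1 + _OFFS6[m, 2]
        if not patch[i, j, k]:
            bg6[nb6, 0] = i
            bg6[nb6, 1] = j
            bg6[nb6, 2] = k
            nb6 += 1
    if nb6 == 0:
        return False
    visited2 = np.zeros(27, np.bool_)
    stack2 = np.empty(27, np.int64)
    sp = 0
    s0 = bg6[0, 0] * 9 + bg6[0, 1] * 3 + bg6[0, 2]
    stack2[sp] = s0
    sp += 1
    visited2[s0] = True
    while sp > 0:
        sp -= 1
        cur = stack2[sp]
        ci, cj, ck = cur // 9, (cur // 3) % 3, cur % 3
        for m in range(6):
            ii, jj, kk = ci + _OFFS6[m, 0], cj + _OFFS6[m, 1], ck + _OFFS6[m, 2]
            if 0 <= ii < 3 and 0 <= jj < 3 and 0 <= kk < 3:
                d18 = abs(ii - 1) + abs(jj - 1) + abs(kk - 1)
                if d18 > 2 or d18 == 0:
                    continue  # stay inside the 18-neighborhood, never
                    # route through the candidate voxel itself
                idx2 = ii * 9 + jj * 3 + kk
                if (not patch[ii, jj, kk]) and not visited2[idx2]:
                    visited2[idx2] = True
                    stack2[sp] = idx2
                    sp += 1
    for m in range(nb6):
        if not visited2[bg6[m, 0] * 9 + bg6[m, 1] * 3 + bg6[m, 2]]:
            return False
    return True


@njit(cache=True)
def _locally_thin(fg, x, y, z):
    """True when the voxel is one voxel thick along some axis (both
    6-neighbors background). Voxels that are already thin at the start
    of a sweep are part of the medial structure and must not erode
    further; evaluating this on a snapshot (not the mutating mask)
    keeps the criterion symmetric in the sweep direction. This is what
    freezes medial surfaces and axes — including even-thickness
    plateaus, where the distance transform carries no ridge
    information."""
    nx, ny, nz = fg.shape
    a = x - 1 >= 0 and fg[x - 1, y, z]
    b = x + 1 < nx and fg[x + 1, y, z]
    if not a and not b:
        return True
    a = y - 1 >= 0 and fg[x, y - 1, z]
    b = y + 1 < ny and fg[x, y + 1, z]
    if not a and not b:
        return True
    a = z - 1 >= 0 and fg[x, y, z - 1]
    b = z + 1 < nz and fg[x, y, z + 1]
    if not a and not b:
        return True
    return False


@njit(cache=True)
def thin_inplace(fg, order_x, order_y, order_z, anchor):
    """Sequential homotopic thinning; repeats the ordered sweep until a
    full pass deletes nothing. Deterministic."""
    changed = True
    while changed:
        changed = False
        snapshot = fg.copy()
        for m in range(order_x.shape[0]):
            x, y, z = order_x[m], order_y[m], order_z[m]
            if not fg[x, y, z] or anchor[x, y, z]:
                continue
            if _locally_thin(snapshot, x, y, z):
                continue
            if is_simple(_patch27(fg, x, y, z)):
                fg[x, y, z] = False
                changed = True


@njit(cache=True)
def neighbor_component_stats(skel):
    """Per skeleton voxel: (number of skeleton 26-neighbors, number of
    26-connected components they form). Used for curve/surface/junction
    tagging."""
    nx, ny, nz = skel.shape
    ncount = np.zeros(skel.shape, np.int16)
    ncomp = np.zeros(skel.shape, np.int16)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not skel[x, y, z]:
                    continue
                patch = _patch27(skel, x, y, z)
                n = 0
                for idx in range(27):
                    if patch[idx // 9, (idx // 3) % 3, idx % 3]:
                        n += 1
                ncount[x, y, z] = n
                # count 26-components of the neighbors
                visited = np.zeros(27, np.bool_)
                comps = 0
                for idx in range(27):
                    i, j, k = idx // 9, (idx // 3) % 3, idx % 3
                    if patch[i, j, k] and not visited[idx]:
                        comps += 1
                        stack = np.empty(27, np.int64)
                        sp = 0
                        stack[sp] = idx
                        sp += 1
                        visited[idx] = True
                        while sp > 0:
                            sp -= 1
                            cur = stack[sp]
                            ci, cj, ck = cur // 9, (cur // 3) % 3, cur % 3
                            for di in range(-1, 2):
                                for dj in range(-1, 2):
                                    for dk in range(-1, 2):
                                        ii, jj, kk = ci + di, cj + dj, ck + dk
                                        if 0 <= ii < 3 and 0 <= jj < 3 and 0 <= kk < 3:
                                            idx2 = ii * 9 + jj * 3 + kk
                                            if patch[ii, jj, kk] and not visited[idx2]:
                                                visited[idx2] = True
                                                stack[sp] = idx2
                                                sp += 1
                ncomp[x, y, z] = comps
    return ncount, ncomp
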