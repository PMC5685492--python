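"""Numba-compiled inner loops: GGMRF smoothing and ICM relabelling sweeps.

Both algorithms are defined as raster-order coordinate updates with in-place
propagation (a voxel's update sees its already-updated predecessors), which
rules out whole-array vectorization; the kernels here keep the sweeps at C
speed.  The pure-Python reference implementations in :mod:`brainseg.mgrf`
(``local_energy``) serve as the oracle the ICM kernel is tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ggmrf_sweep(vals, orig, offsets, weights, data_pow, prior_pow, rho_alpha, Q):
    """One raster-order GGMRF sweep; returns number of changed voxels.

    ``data_pow[d] = d**alpha`` and ``prior_pow[d] = d**beta`` are precomputed
    for integer grey differences d in [0, Q-1]; only nonzero (brain) voxels are
    updated and only nonzero neighbours contribute to the prior term.
    """
    X, Y, Z = vals.shape
    n_off = offsets.shape[0]
    changed = 0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                if vals[x, y, z] == 0:
                    continue
                g0 = orig[x, y, z]
                best_q = vals[x, y, z]
                best_f = 1e300
                for q in range(1, Q):
                    f = data_pow[abs(q - g0)]
                    for i in range(n_off):
                        nx = x + offsets[i, 0]
                        ny = y + offsets[i, 1]
                        nz = z + offsets[i, 2]
                        if nx < 0 or ny < 0 or nz < 0 or nx >= X or ny >= Y or nz >= Z:
                            continue
                        nv = vals[nx, ny, nz]
                        if nv == 0:
                            continue
                        f += rho_alpha * weights[i] * prior_pow[abs(q - nv)]
                    if f < best_f:
                        best_f = f
                        best_q = q
                if best_q != vals[x, y, z]:
                    changed += 1
                vals[x, y, z] = best_q
    return changed


@njit(cache=True, inline="always")
def _gibbs_local(m, x, y, z, lab, off2, v2, dir3, v3, quad_e1, quad_e2, v4):
    """Sum of clique potentials over all cliques containing (x,y,z), with the
    voxel's label set to ``lab``.  Cliques touching background (label 0) are
    skipped; potentials depend only on the equality pattern of the labels."""
    X, Y, Z = m.shape
    e = 0.0
    if lab == 0:
        return 0.0
    # pairwise: each directed 26-neighbour offset is one clique through p
    for i in range(off2.shape[0]):
        nx = x + off2[i, 0]
        ny = y + off2[i, 1]
        nz = z + off2[i, 2]
        if nx < 0 or ny < 0 or nz < 0 or nx >= X or ny >= Y or nz >= Z:
            continue
        nv = m[nx, ny, nz]
        if nv == 0:
            continue
        if nv == lab:
            e += v2[i]
        else:
            e -= v2[i]
    # collinear triples {p+t*d, p+(t+1)*d, p+(t+2)*d}, t = -2..0
    for i in range(dir3.shape[0]):
        dx = dir3[i, 0]
        dy = dir3[i, 1]
        dz = dir3[i, 2]
        for t in range(-2, 1):
            ok = True
            eq = True
            l0 = 0
            for k in range(3):
                px = x + (t + k) * dx
                py = y + (t + k) * dy
                pz = z + (t + k) * dz
                if px < 0 or py < 0 or pz < 0 or px >= X or py >= Y or pz >= Z:
                    ok = False
                    break
                if px == x and py == y and pz == z:
                    lv = lab
                else:
                    lv = m[px, py, pz]
                if lv == 0:
                    ok = False
                    break
                if k == 0:
                    l0 = lv
                elif lv != l0:
                    eq = False
            if not ok:
                continue
            if eq:
                e += v3[i]
            else:
                e -= v3[i]
    # planar 2x2 quads; anchors at the four corners that keep p inside
    labs = np.empty(4, dtype=np.int64)
    for i in range(quad_e1.shape[0]):
        for a in range(-1, 1):
            for b in range(-1, 1):
                ok = True
                for k in range(4):
                    c1 = a + (k & 1)
                    c2 = b + (k >> 1)
                    px = x + c1 * quad_e1[i, 0] + c2 * quad_e2[i, 0]
                    py = y + c1 * quad_e1[i, 1] + c2 * quad_e2[i, 1]
                    pz = z + c1 * quad_e1[i, 2] + c2 * quad_e2[i, 2]
                    if px < 0 or py < 0 or pz < 0 or px >= X or py >= Y or pz >= Z:
                        ok = False
                        break
                    if px == x and py == y and pz == z:
                        labs[k] = lab
                    else:
                        labs[k] = m[px, py, pz]
                    if labs[k] == 0:
                        ok = False
                        break
                if not ok:
                    continue
                npairs = 0
                for k in range(4):
                    for kk in range(k + 1, 4):
                        if labs[k] == labs[kk]:
                            npairs += 1
                if npairs == 6:
                    e += v4[i, 0]
                elif npairs == 3:
                    e += v4[i, 1]
                else:
                    e += v4[i, 2]
    return e


@njit(cache=True)
def icm_sweep(m, lp, off2, v2, dir3, v3, quad_e1, quad_e2, v4):
    """One raster-order ICM sweep (in place); returns number of relabelled voxels.

    ``lp[x, y, z, l]`` carries log p(g|l) + log p_sp(l); the Gibbs part is
    recomputed per candidate label.  A voxel changes only on strict objective
    improvement, so sweeps are monotone coordinate ascent.
    """
    X, Y, Z = m.shape
    changed = 0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                cur = m[x, y, z]
                if cur == 0:
                    continue
                best_l = cur
                best_s = lp[x, y, z, cur] + _gibbs_local(
                    m, x, y, z, cur, off2, v2, dir3, v3, quad_e1, quad_e2, v4
                )
                for lab in range(1, 4):
                    if lab == cur:
                        continue
                    s = lp[x, y, z, lab] + _gibbs_local(
                        m, x, y, z, lab, off2, v2, dir3, v3, quad_e1, quad_e2, v4
                    )
                    if s > best_s:
                        best_s = s
                        best_l = lab
                if best_l != cur:
                    m[x, y, z] = best_l
                    changed += 1
    return changed
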