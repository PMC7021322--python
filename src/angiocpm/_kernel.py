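"""Compiled inner loop of the CPM sweep.

The kernel mirrors, decision for decision, the pure-Python attempt loop in
:mod:`angiocpm.lattice` (which remains the readable reference and the
fallback when numba is unavailable): same pre-drawn random streams, same
energy terms, same connectivity and annihilation guards.  Per-cell geometry
caches travel as flat arrays indexed by spin label.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _ring_connected(spin, jx, jy, t, nx, ny):
    """Moore-ring connectivity of cell t's pixels around (jx, jy)."""
    rx = np.empty(8, np.int64)
    ry = np.empty(8, np.int64)
    m = 0
    for k in range(8):
        if k == 0:
            dx, dy = 1, 0
        elif k == 1:
            dx, dy = -1, 0
        elif k == 2:
            dx, dy = 0, 1
        elif k == 3:
            dx, dy = 0, -1
        elif k == 4:
            dx, dy = 1, 1
        elif k == 5:
            dx, dy = 1, -1
        elif k == 6:
            dx, dy = -1, 1
        else:
            dx, dy = -1, -1
        qx = jx + dx
        qy = jy + dy
        if 0 <= qx < nx and 0 <= qy < ny and spin[qx, qy] == t:
            rx[m] = dx
            ry[m] = dy
            m += 1
    if m <= 1:
        return True
    seen = np.zeros(8, np.uint8)
    stack = np.empty(8, np.int64)
    stack[0] = 0
    seen[0] = 1
    top = 1
    count = 1
    while top > 0:
        top -= 1
        i = stack[top]
        for k in range(m):
            if seen[k] == 0 and abs(rx[i] - rx[k]) <= 1 and abs(ry[i] - ry[k]) <= 1:
                seen[k] = 1
                count += 1
                stack[top] = k
                top += 1
    return count == m


@njit(cache=True, inline="always")
def _shape_e(n, sx, sy, sxx, syy, sxy, perim, h, A, P, L, ra, rp, rl):
    a = n * h * h
    p = perim * h
    var_x = sxx / n - (sx / n) ** 2
    var_y = syy / n - (sy / n) ** 2
    cov = sxy / n - (sx / n) * (sy / n)
    half_tr = 0.5 * (var_x + var_y)
    disc = ((0.5 * (var_x - var_y)) ** 2 + cov * cov) ** 0.5
    lam = half_tr + disc
    if lam < 0.0:
        lam = 0.0
    length = 4.0 * lam ** 0.5 * h
    return (ra * ((a - A) / A) ** 2 + rp * ((p - P) / P) ** 2
            + rl * ((length - L) / L) ** 2)


@njit(cache=True)
def sweep_kernel(spin, idx, dirs, unif,
                 nn, sx, sy, sxx, syy, sxy, perim,
                 A, P, L, rlen, rchem, rdur, rpers, pcx, pcy, dlev,
                 h, T, rho_area, rho_perim, rho_cc, rho_ce, adh_moore, conn_check,
                 has_fields, c_pix, h1f, h2f, v1x, v1y, v2x, v2y,
                 case_b, rho_chem0, max_d, alpha_chem):
    """Run one sweep of copy attempts in place; returns (n_eval, n_accept)."""
    nx, ny = spin.shape
    n_eval = 0
    n_acc = 0
    for k in range(idx.shape[0]):
        p = idx[k]
        ix = p // ny
        iy = p % ny
        d = dirs[k]
        if d == 0:
            dx, dy = 1, 0
        elif d == 1:
            dx, dy = -1, 0
        elif d == 2:
            dx, dy = 0, 1
        else:
            dx, dy = 0, -1
        jx = ix + dx
        jy = iy + dy
        if jx < 0 or jx >= nx or jy < 0 or jy >= ny:
            continue
        s = spin[ix, iy]
        t = spin[jx, jy]
        if s == t:
            continue
        if t != 0:
            if nn[t] <= 1.0:
                continue
            if conn_check and not _ring_connected(spin, jx, jy, t, nx, ny):
                continue
        n_eval += 1
        px = jx + 0.5
        py = jy + 0.5
        dH = 0.0
        # adhesion over the chosen neighborhood of the target pixel
        n_offs = 8 if adh_moore else 4
        for o in range(n_offs):
            if o == 0:
                ox, oy = 1, 0
            elif o == 1:
                ox, oy = -1, 0
            elif o == 2:
                ox, oy = 0, 1
            elif o == 3:
                ox, oy = 0, -1
            elif o == 4:
                ox, oy = 1, 1
            elif o == 5:
                ox, oy = 1, -1
            elif o == 6:
                ox, oy = -1, 1
            else:
                ox, oy = -1, -1
            qx = jx + ox
            qy = jy + oy
            if 0 <= qx < nx and 0 <= qy < ny:
                u = spin[qx, qy]
                if u != s:
                    dH += rho_cc if (u != 0 and s != 0) else rho_ce
                if u != t:
                    dH -= rho_cc if (u != 0 and t != 0) else rho_ce
        # perimeter-edge changes
        dps = 0
        dpt = 0
        for o in range(4):
            if o == 0:
                ox, oy = 1, 0
            elif o == 1:
                ox, oy = -1, 0
            elif o == 2:
                ox, oy = 0, 1
            else:
                ox, oy = 0, -1
            qx = jx + ox
            qy = jy + oy
            if 0 <= qx < nx and 0 <= qy < ny:
                u = spin[qx, qy]
            else:
                u = -1
            if u == s:
                dps -= 1
            else:
                dps += 1
            if u == t:
                dpt += 1
            else:
                dpt -= 1
        # shape terms
        if s != 0:
            dH += _shape_e(nn[s] + 1.0, sx[s] + px, sy[s] + py,
                           sxx[s] + px * px, syy[s] + py * py,
                           sxy[s] + px * py, perim[s] + dps, h,
                           A[s], P[s], L[s], rho_area, rho_perim, rlen[s]) \
                - _shape_e(nn[s], sx[s], sy[s], sxx[s], syy[s], sxy[s],
                           perim[s], h, A[s], P[s], L[s], rho_area, rho_perim, rlen[s])
        if t != 0:
            dH += _shape_e(nn[t] - 1.0, sx[t] - px, sy[t] - py,
                           sxx[t] - px * px, syy[t] - py * py,
                           sxy[t] - px * py, perim[t] + dpt, h,
                           A[t], P[t], L[t], rho_area, rho_perim, rlen[t]) \
                - _shape_e(nn[t], sx[t], sy[t], sxx[t], syy[t], sxy[t],
                           perim[t], h, A[t], P[t], L[t], rho_area, rho_perim, rlen[t])
        if has_fields:
            fdx = float(dx)
            fdy = float(dy)
            # durotaxis: source-cell extension at the target pixel,
            # target-cell retraction at the source pixel
            if s != 0 and rdur[s] != 0.0:
                pr1 = v1x[jx, jy] * fdx + v1y[jx, jy] * fdy
                pr2 = v2x[jx, jy] * fdx + v2y[jx, jy] * fdy
                dH -= rdur[s] * (h1f[jx, jy] * pr1 * pr1 + h2f[jx, jy] * pr2 * pr2)
            if t != 0 and rdur[t] != 0.0:
                pr1 = v1x[ix, iy] * fdx + v1y[ix, iy] * fdy
                pr2 = v2x[ix, iy] * fdx + v2y[ix, iy] * fdy
                dH += rdur[t] * (h1f[ix, iy] * pr1 * pr1 + h2f[ix, iy] * pr2 * pr2)
            # chemotaxis
            if case_b:
                if max_d > 0.0:
                    if s != 0 and t != 0:
                        dl = 0.5 * (dlev[s] + dlev[t])
                    elif s != 0:
                        dl = dlev[s]
                    else:
                        dl = dlev[t]
                    rho_c = rho_chem0 * dl / max_d
                else:
                    rho_c = 0.0
            else:
                rho_c = rchem[s] if s != 0 else rchem[t]
            if rho_c != 0.0:
                c_src = c_pix[ix, iy]
                dH -= rho_c * (c_pix[jx, jy] - c_src) / (1.0 + alpha_chem * c_src)
            # persistent motion of incubating tips (extensions only)
            if s != 0 and rpers[s] != 0.0:
                dH -= rpers[s] * (pcx[s] * fdx + pcy[s] * fdy)
        if dH > 0.0 and unif[k] >= math.exp(-dH / T):
            continue
        # accept
        n_acc += 1
        spin[jx, jy] = s
        if s != 0:
            nn[s] += 1.0
            sx[s] += px
            sy[s] += py
            sxx[s] += px * px
            syy[s] += py * py
            sxy[s] += px * py
            perim[s] += dps
        if t != 0:
            nn[t] -= 1.0
            sx[t] -= px
            sy[t] -= py
            sxx[t] -= px * px
            syy[t] -= py * py
            sxy[t] -= px * py
            perim[t] += dpt
    return n_eval, n_acc
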