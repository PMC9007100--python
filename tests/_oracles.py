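"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the production implementations:
the debark oracle enumerates every window position and spine pair directly;
the climb oracle is an exact dynamic program over lattice polylines with a
bitmask of already-penalized spines (each spine counted once per path, as in
the production cost function).
"""

from __future__ import annotations

import math

import numpy as np


# -- debark ---------------------------------------------------------------------


def debark_oracle(spine_map, bite_size, margin=1.0, max_width_fraction=0.25,
                  grid_step=0.25):
    """(accessible_fraction, ring_risk) by direct enumeration."""
    C = spine_map.surface.circumference_cm
    H = spine_map.surface.height_cm
    w = min(bite_size, max_width_fraction * C)
    h = bite_size
    nx = max(1, int(round(C / grid_step)))
    gx = C / nx
    ny = max(1, int(round(H / grid_step)))
    gy = H / ny
    n_wy = int(math.floor((H - h) / gy + 1e-9)) + 1
    sx = spine_map.x
    sy = spine_map.y

    def window_free(wx, wy):
        for a, b in zip(sx, sy):
            d = abs(a - (wx + w / 2.0)) % C
            d = min(d, C - d)
            if d <= w / 2.0 + margin + 1e-9 and wy - margin - 1e-9 <= b <= wy + h + margin + 1e-9:
                return False
        return True

    acc = np.zeros((n_wy, nx), dtype=bool)
    for iy in range(n_wy):
        for ix in range(nx):
            acc[iy, ix] = window_free(ix * gx, iy * gy)

    covered = np.zeros((ny, nx), dtype=bool)
    for iy in range(n_wy):
        wy = iy * gy
        for ix in range(nx):
            if not acc[iy, ix]:
                continue
            wx = ix * gx
            for cy in range(ny):
                ccy = (cy + 0.5) * gy
                if not (wy - 1e-9 <= ccy <= wy + h + 1e-9):
                    continue
                for cx in range(nx):
                    ccx = (cx + 0.5) * gx
                    off = (ccx - wx) % C
                    if off <= w + 1e-9:  # centre on the window edge counts
                        covered[cy, cx] = True
    frac = covered.mean()

    ring_ok = 0
    for iy in range(n_wy):
        cell_cov = np.zeros(nx, dtype=bool)
        for ix in range(nx):
            if not acc[iy, ix]:
                continue
            for cx in range(nx):
                off = ((cx + 0.5) * gx - ix * gx) % C
                if off <= w + 1e-9:
                    cell_cov[cx] = True
        if cell_cov.all():
            ring_ok += 1
    return float(frac), float(ring_ok / n_wy)


# -- climb ------------------------------------------------------------------------


def _edge_hit_masks(x1s, y1, x2s, y2, sx, sy, C, r):
    """Bitmask of spines within distance r of each edge; x1s/x2s: (nx,)."""
    dx = (x2s - x1s + C / 2.0) % C - C / 2.0  # (nx,)
    dy = y2 - y1
    seglen2 = dx * dx + dy * dy
    rel = (sx[None, :] - x1s[:, None] + C / 2.0) % C - C / 2.0  # (nx, m)
    py = (sy - y1)[None, :]
    best = np.full(rel.shape, np.inf)
    for j in (-C, 0.0, C):
        px = rel + j
        t = np.clip((px * dx[:, None] + py * dy) / seglen2[:, None], 0.0, 1.0)
        d2 = (px - t * dx[:, None]) ** 2 + (py - t * dy) ** 2
        best = np.minimum(best, d2)
    hits = best <= r * r + 1e-9
    return hits @ (1 << np.arange(sx.size, dtype=np.int64))


def _popcount(v):
    try:
        return np.bitwise_count(v).astype(float)
    except AttributeError:  # pragma: no cover
        out = np.zeros(v.shape)
        for b in range(63):
            out += (v >> b) & 1
        return out


def climb_dp_oracle(spine_map, paw_size, penalty=10.0, speed=1.0,
                    mesh=0.25, max_shift_cm=2.0):
    """Exact minimum cost over monotone lattice polylines.

    Nodes are (column, row) on a ``mesh``-spaced lattice; edges climb one row
    and shift at most ``max_shift_cm`` circumferentially.  The DP state is
    (column, set of spines already penalized), so each spine is charged once
    per path, exactly as in the production cost function.  Feasible only for
    small maps (<= ~12 spines).
    """
    C = spine_map.surface.circumference_cm
    H = spine_map.surface.height_cm
    m = spine_map.n_spines
    if m > 12:
        raise ValueError("bitmask DP limited to <= 12 spines")
    nx = max(1, int(round(C / mesh)))
    gx = C / nx
    ny = int(round(H / mesh))
    gy = H / ny
    max_s = max(1, int(round(max_shift_cm / gx)))
    shifts = np.arange(-max_s, max_s + 1)
    r = paw_size / 2.0
    sx, sy = spine_map.x, spine_map.y
    n_masks = 1 << m
    masks = np.arange(n_masks, dtype=np.int64)

    seg_len = np.sqrt((shifts * gx) ** 2 + gy**2)
    xs = np.arange(nx) * gx

    D = np.full((nx, n_masks), np.inf)
    D[:, 0] = 0.0
    for row in range(ny):
        y1, y2 = row * gy, (row + 1) * gy
        Dn = np.full((nx, n_masks), np.inf)
        for si, s in enumerate(shifts):
            cost = seg_len[si] / speed
            x2s = (xs + s * gx) % C
            if m:
                hms = _edge_hit_masks(xs, y1, x2s, y2, sx, sy, C, r)
            else:
                hms = np.zeros(nx, dtype=np.int64)
            for x1 in range(nx):
                col = D[x1]
                x2 = (x1 + s) % nx
                hm = int(hms[x1])
                if hm == 0:
                    np.minimum(Dn[x2], col + cost, out=Dn[x2])
                else:
                    newly = np.int64(hm) & ~masks
                    vals = col + cost + penalty * _popcount(newly)
                    np.minimum.at(Dn[x2], masks | hm, vals)
        D = Dn
    return float(np.min(D))
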