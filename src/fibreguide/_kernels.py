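"""Compiled inner loops for the per-step hot paths.

Pure computational kernels: all-pairs capped Lennard-Jones forces,
close-neighbour counts, and the tent-kernel deposition sums.  Numerics
are IEEE-strict (no fastmath) so results are bit-reproducible and match
a straightforward double-loop evaluation; the periodic minimum image is
applied pairwise, exploiting that the interaction ranges are far below
half the domain.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pairwise_forces(pos, L, eps, sigma, F0, rmax):
    """Net capped Lennard-Jones force on every cell; Newton-symmetric.

    Returns ``(forces, coincident_pairs)``: coincident pairs (separation
    < 1e-9 um) are reported in ascending (i, j) order for the caller to
    resolve with random kicks; they contribute no deterministic force.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    coinc = np.empty((n, 2), np.int64)
    ncoinc = 0
    s6 = sigma ** 6
    rmax2 = rmax * rmax
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.rint(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L * np.rint(dy / L)
            r2 = dx * dx + dy * dy
            if r2 > rmax2:
                continue
            r = np.sqrt(r2)
            if r < 1e-9:
                if ncoinc < n:
                    coinc[ncoinc, 0] = i
                    coinc[ncoinc, 1] = j
                    ncoinc += 1
                continue
            f = 24.0 * eps * s6 * (2.0 * s6 / r ** 13 - 1.0 / r ** 7)
            if f > F0:
                f = F0
            fx = f * dx / r
            fy = f * dy / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy
    return forces, coinc[:ncoinc]


@njit(cache=True)
def neighbour_counts(pos, L, rc):
    """Number of other cells within ``rc`` (inclusive, 1e-9 um slack)."""
    n = pos.shape[0]
    counts = np.zeros(n, np.int64)
    rc2 = (rc + 1e-9) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.rint(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L * np.rint(dy / L)
            if dx * dx + dy * dy <= rc2:
                counts[i] += 1
                counts[j] += 1
    return counts


@njit(cache=True)
def deposit_sums(pos, units, valid, nx, ny, delta, radius,
                 wsum, sxx, sxy, syy, need_secretion):
    """Accumulate tent-kernel weight sums and secretion tensors.

    ``wsum`` and the ``s``-arrays are flat (nx*ny) accumulators indexed
    ``ix * ny + iy``; only nodes within ``radius`` of some cell receive
    contributions.  Returns the maximum per-node weight sum (for the
    degradation stability check).
    """
    n = pos.shape[0]
    nr = int(np.ceil(radius / delta))
    maxw = 0.0
    for c in range(n):
        bx = int(np.floor(pos[c, 0] / delta))
        by = int(np.floor(pos[c, 1] / delta))
        ux = units[c, 0]
        uy = units[c, 1]
        sec = need_secretion and valid[c]
        for k1 in range(-nr, nr + 2):
            dx = (bx + k1) * delta - pos[c, 0]
            ix = (bx + k1) % nx
            for k2 in range(-nr, nr + 2):
                dy = (by + k2) * delta - pos[c, 1]
                r = np.sqrt(dx * dx + dy * dy)
                if r > radius:
                    continue
                w = 1.0 - r / radius
                idx = ix * ny + (by + k2) % ny
                wsum[idx] += w
                if wsum[idx] > maxw:
                    maxw = wsum[idx]
                if sec:
                    sxx[idx] += w * ux * ux
                    sxy[idx] += w * ux * uy
                    syy[idx] += w * uy * uy
    return maxw
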