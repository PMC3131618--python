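"""Numba kernels for (26, 6) digital topology on 3x3x3 neighborhoods.

Conventions: foreground (bone) uses 26-connectivity, background uses
6-connectivity — the standard complementary pair that makes the simple-point
test well defined. For a voxel x with punctured neighborhood N26*(x):

* ``A`` = number of 26-connected components of foreground in N26*(x)
  (every voxel of N26* is 26-adjacent to x, so all components count);
* ``B`` = number of 6-connected components of background restricted to the
  18-neighborhood that are 6-adjacent to x (i.e. contain a face neighbor).

x is a *simple point* — removable without changing the number of connected
components, tunnels or cavities — iff ``A == 1 and B == 1``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---- static neighborhood tables ------------------------------------------
# flat index k = (dz+1)*9 + (dy+1)*3 + (dx+1); center is 13
_OFF = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)],
    dtype=np.int64,
)
CENTER = 13

_cheb = np.max(np.abs(_OFF[:, None, :] - _OFF[None, :, :]), axis=2)
_manh = np.sum(np.abs(_OFF[:, None, :] - _OFF[None, :, :]), axis=2)

ADJ26 = (_cheb == 1).astype(np.uint8)  # Chebyshev distance 1 (diagonal is 0)

IN_N18 = ((np.abs(_OFF).max(axis=1) == 1) & (np.abs(_OFF).sum(axis=1) <= 2)).astype(
    np.uint8
)
ADJ6 = (_manh == 1).astype(np.uint8)
FACE_IDX = np.flatnonzero(np.abs(_OFF).sum(axis=1) == 1).astype(np.int64)


@njit(cache=True)
def _count_A(nb, adj26):
    """26-components of foreground in the punctured 27-neighborhood."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    count = 0
    for i in range(27):
        if i == CENTER or nb[i] == 0 or visited[i]:
            continue
        count += 1
        top = 0
        stack[top] = i
        visited[i] = 1
        top = 1
        while top > 0:
            top -= 1
            c = stack[top]
            for j in range(27):
                if j == CENTER or nb[j] == 0 or visited[j] or adj26[c, j] == 0:
                    continue
                visited[j] = 1
                stack[top] = j
                top += 1
    return count


@njit(cache=True)
def _count_B(nb, adj6, in_n18, face_idx):
    """6-components of background in N18 that contain a face neighbor."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    count = 0
    for fi in range(6):
        i = face_idx[fi]
        if nb[i] != 0 or visited[i]:
            continue
        count += 1
        top = 0
        stack[top] = i
        visited[i] = 1
        top = 1
        while top > 0:
            top -= 1
            c = stack[top]
            for j in range(27):
                if in_n18[j] == 0 or nb[j] != 0 or visited[j] or adj6[c, j] == 0:
                    continue
                visited[j] = 1
                stack[top] = j
                top += 1
    return count


@njit(cache=True)
def _gather(m, z, y, x, nb):
    cnt = 0
    k = 0
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                v = m[z + dz, y + dy, x + dx]
                nb[k] = v
                k += 1
                cnt += v
    cnt -= nb[CENTER]
    nb[CENTER] = 0
    return cnt  # number of foreground 26-neighbors


@njit(cache=True)
def _is_thin(m, z, y, x, d):
    """Both axis-``d`` neighbors background (voxel is 1-thick along d)."""
    if d == 0:
        return m[z - 1, y, x] == 0 and m[z + 1, y, x] == 0
    if d == 1:
        return m[z, y - 1, x] == 0 and m[z, y + 1, x] == 0
    return m[z, y, x - 1] == 0 and m[z, y, x + 1] == 0


@njit(cache=True)
def _sheet_protected(m, z, y, x):
    """Whether the voxel belongs to a 1-voxel-thick sheet (incl. its edge).

    The voxel must be thin along some axis d, and its foreground neighbors
    that are *also* thin along d must span two non-collinear directions.
    A flat or tilted 1-voxel sheet (and its edge/corner voxels) satisfies
    this; the convex rim voxels of a still-thick body do not, so thinning
    does not stall before bodies are actually thin.
    """
    for d in range(3):
        if not _is_thin(m, z, y, x, d):
            continue
        r0 = 0
        r1 = 0
        r2 = 0
        have_ref = False
        for dz in range(-1, 2):
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    if dz == 0 and dy == 0 and dx == 0:
                        continue
                    if m[z + dz, y + dy, x + dx] == 0:
                        continue
                    if not _is_thin(m, z + dz, y + dy, x + dx, d):
                        continue
                    if not have_ref:
                        r0, r1, r2 = dz, dy, dx
                        have_ref = True
                    else:
                        # cross product != 0 -> non-collinear with reference
                        cz = r1 * dx - r2 * dy
                        cy = r2 * dz - r0 * dx
                        cx = r0 * dy - r1 * dz
                        if cz != 0 or cy != 0 or cx != 0:
                            return True
    return False


@njit(cache=True)
def _thin_pass(m, cand, adj26, adj6, in_n18, face_idx, protect_sheets):
    """One sequential pass over sorted candidates; removes simple points.

    Protections (re-evaluated on the current state, so the final skeleton is
    a fixed point and re-skeletonization is the identity):
      * curve ends / isolated voxels (<= 1 foreground neighbor);
      * sheet voxels (see :func:`_sheet_protected`), which keeps plates as
        1-voxel sheets instead of eroding them to lines.
    """
    ny = m.shape[1]
    nx = m.shape[2]
    nb = np.empty(27, np.uint8)
    removed = 0
    for t in range(cand.size):
        f = cand[t]
        x = f % nx
        y = (f // nx) % ny
        z = f // (nx * ny)
        if m[z, y, x] == 0:
            continue
        cnt = _gather(m, z, y, x, nb)
        if cnt <= 1:
            continue
        if protect_sheets and _sheet_protected(m, z, y, x):
            continue
        if _count_A(nb, adj26) != 1:
            continue
        if _count_B(nb, adj6, in_n18, face_idx) != 1:
            continue
        m[z, y, x] = 0
        removed += 1
    return removed


@njit(cache=True)
def _topo_numbers(m, idx, adj26, adj6, in_n18, face_idx):
    """Per-voxel (neighbor count, A, B) for the given flat indices."""
    ny = m.shape[1]
    nx = m.shape[2]
    nb = np.empty(27, np.uint8)
    out = np.empty((idx.size, 3), np.int64)
    for t in range(idx.size):
        f = idx[t]
        x = f % nx
        y = (f // nx) % ny
        z = f // (nx * ny)
        cnt = _gather(m, z, y, x, nb)
        out[t, 0] = cnt
        out[t, 1] = _count_A(nb, adj26)
        out[t, 2] = _count_B(nb, adj6, in_n18, face_idx)
    return out


@njit(cache=True)
def _thin_pass_curve(m, cand, shield, adj26, adj6, in_n18, face_idx):
    """Curve-thinning pass: erode ribbons and small webs to 1-wide curves.

    ``shield`` marks voxels belonging to genuine sheets (large connected
    regions of B >= 2 voxels, dilated to include their edges); those are
    untouched. Everything else is thinned to curves under endpoint and
    simple-point protection.
    """
    ny = m.shape[1]
    nx = m.shape[2]
    nb = np.empty(27, np.uint8)
    removed = 0
    for t in range(cand.size):
        f = cand[t]
        x = f % nx
        y = (f // nx) % ny
        z = f // (nx * ny)
        if m[z, y, x] == 0 or shield[z, y, x]:
            continue
        cnt = _gather(m, z, y, x, nb)
        if cnt <= 1:
            continue
        if _count_A(nb, adj26) != 1:
            continue
        if _count_B(nb, adj6, in_n18, face_idx) != 1:
            continue
        m[z, y, x] = 0
        removed += 1
    return removed


def topo_numbers(mask: np.ndarray, indices: np.ndarray | None = None) -> np.ndarray:
    """(neighbor count, A, B) for each foreground voxel of ``mask``.

    Returns an ``(n, 3)`` array aligned with ``indices`` (flat indices into
    the *unpadded* mask; defaults to all foreground voxels in raster order).
    """
    mask = np.asarray(mask, bool)
    if indices is None:
        indices = np.flatnonzero(mask)
    m = np.pad(mask, 1).astype(np.uint8)
    nz, ny, nx = mask.shape
    z, rem = np.divmod(indices, ny * nx)
    y, x = np.divmod(rem, nx)
    pidx = (z + 1) * (m.shape[1] * m.shape[2]) + (y + 1) * m.shape[2] + (x + 1)
    return _topo_numbers(m, pidx.astype(np.int64), ADJ26, ADJ6, IN_N18, FACE_IDX)


def is_simple(mask: np.ndarray, voxel: tuple[int, int, int]) -> bool:
    """Whether removing ``voxel`` preserves (26, 6) digital topology."""
    z, y, x = voxel
    flat = np.array([z * mask.shape[1] * mask.shape[2] + y * mask.shape[2] + x])
    cnt, a, b = topo_numbers(mask, flat)[0]
    return bool(a == 1 and b == 1)
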