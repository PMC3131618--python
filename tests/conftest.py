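"""Shared fixtures: small structured volumes and independent topology oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from itsmorph.volume import BinaryVolume

VOX = 0.082  # mm, nominal scanner voxel

_STRUCT26 = np.ones((3, 3, 3), bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def topology_counts(mask: np.ndarray) -> tuple[int, int, int]:
    """(components, tunnels, cavities) for 26-connected foreground.

    Independent oracle: components and cavities by labeling, tunnels from
    the Euler characteristic (chi = c - t + cav) computed by skimage.
    """
    from skimage.measure import euler_number

    if not mask.any():
        return 0, 0, 0
    c = ndimage.label(mask, structure=_STRUCT26)[1]
    cav = ndimage.label(~np.pad(mask, 1), structure=_STRUCT6)[1] - 1
    chi = euler_number(mask, connectivity=3)
    return int(c), int(c + cav - chi), int(cav)


def line_volume(length=10, pad=1) -> np.ndarray:
    m = np.zeros((1 + 2 * pad, 1 + 2 * pad, length + 2 * pad), bool)
    m[pad, pad, pad : pad + length] = True
    return m


def sheet_volume(ny=10, nx=10, pad=2) -> np.ndarray:
    m = np.zeros((1 + 2 * pad, ny + 2 * pad, nx + 2 * pad), bool)
    m[pad, pad : pad + ny, pad : pad + nx] = True
    return m


def strut_volume(shape, p0, p1, radius) -> np.ndarray:
    """Solid finite cylinder between two points (voxel-center containment)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    a = axis / length
    zz, yy, xx = np.indices(shape)
    d = np.stack([zz, yy, xx], -1).reshape(-1, 3) - p0
    t = d @ a
    radial = np.linalg.norm(d - np.outer(t, a), axis=1)
    inside = (radial <= radius) & (t >= 0) & (t <= length)
    return inside.reshape(shape)


def structured_phantoms(n: int, max_side: int = 32) -> list[np.ndarray]:
    """Deterministic battery of small topology-rich test volumes."""
    rng = np.random.default_rng(20260101)
    vols: list[np.ndarray] = []
    # structured: slab, plate+rod, crossing struts, hollow torus, ring
    slab = np.zeros((12, 20, 20), bool)
    slab[4:8, 2:18, 2:18] = True
    vols.append(slab)
    pr = sheet_volume(14, 14, pad=3)
    pr[3:10, 10, 10] = True
    vols.append(pr)
    cross = strut_volume((24, 24, 24), (2, 4, 12), (21, 20, 12), 1.3) | strut_volume(
        (24, 24, 24), (2, 20, 12), (21, 4, 12), 1.3
    )
    vols.append(cross)
    zz, yy, xx = np.indices((9, 26, 26))
    rad = np.sqrt((yy - 12.5) ** 2 + (xx - 12.5) ** 2)
    vols.append(((rad - 8.0) ** 2 + (zz - 4) ** 2) <= 2.4**2)  # torus (1 tunnel)
    ring = np.zeros((3, 16, 16), bool)
    ring[1, 2:14, 2:14] = True
    ring[1, 5:11, 5:11] = False
    vols.append(ring)
    # random blobs, morphologically closed so they have plates/rods/tunnels
    while len(vols) < n:
        side = int(rng.integers(16, max_side + 1))
        raw = rng.random((side,) * 3) < float(rng.uniform(0.25, 0.45))
        blob = ndimage.binary_closing(raw, np.ones((2, 2, 2), bool))
        blob = ndimage.binary_opening(blob, _STRUCT6)
        if blob.sum() >= 20:
            vols.append(blob)
    return vols[:n]


@pytest.fixture(scope="session")
def phantom_battery():
    return structured_phantoms(30)


@pytest.fixture
def binary(request):
    def make(mask):
        return BinaryVolume(np.asarray(mask, bool), VOX)

    return make
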