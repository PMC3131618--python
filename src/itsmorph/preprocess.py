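"""Image preparation: edge-enhancing filter, global threshold, cube extraction.

The scanner's segmentation chain is a Laplace-Hamming filter followed by a
global threshold at 40% of the maximal grayscale value. The manufacturer's
kernel constants are not public, so the filter here is a frequency-domain
Hamming-windowed low-pass multiplied by a weighted Laplacian enhancement,
with both parameters exposed; the pipeline equally accepts pre-thresholded
binary input, so every downstream plate/rod and stiffness result is
independent of the filter choice.
"""

from __future__ import annotations

import numpy as np

from .volume import BinaryVolume, GrayVolume

__all__ = [
    "laplace_hamming_filter",
    "global_threshold",
    "extract_cubic_subvolume",
]


def laplace_hamming_filter(
    gray: GrayVolume, cutoff: float = 0.4, laplace_weight: float = 0.5
) -> GrayVolume:
    """Edge-enhancing smoothing filter applied in the frequency domain.

    Transfer function ``T(rho) = W(rho) * (1 + w * (rho/0.5)**2)`` where
    ``rho`` is radial spatial frequency in cycles/sample (Nyquist = 0.5),
    ``W`` a Hamming-window low-pass with the given ``cutoff`` (cycles/sample,
    in (0, 0.5]), and ``w`` the Laplacian enhancement weight (the ``rho**2``
    term is the spectrum of a negated Laplacian). ``T(0) = 1``, so constant
    volumes pass through unchanged; the filter is a circular convolution,
    deterministic given its parameters.
    """
    if not (0 < cutoff <= 0.5):
        raise ValueError(f"cutoff must lie in (0, 0.5] cycles/sample, got {cutoff}")
    data = np.asarray(gray.data, dtype=np.float64)
    freqs = [np.fft.fftfreq(n) for n in data.shape]
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    rho = np.sqrt(fz**2 + fy**2 + fx**2)
    window = np.where(rho <= cutoff, 0.54 + 0.46 * np.cos(np.pi * rho / cutoff), 0.0)
    transfer = window * (1.0 + laplace_weight * (rho / 0.5) ** 2)
    out = np.fft.ifftn(np.fft.fftn(data) * transfer).real
    res = GrayVolume(out, gray.voxel_size_mm)
    res.meta = dict(gray.meta)
    res.meta["laplace_hamming"] = {"cutoff": cutoff, "laplace_weight": laplace_weight}
    return res


def filter_kernel(shape, cutoff: float = 0.4, laplace_weight: float = 0.5) -> np.ndarray:
    """Spatial (circular) kernel of the filter: its response to a unit impulse."""
    delta = np.zeros(shape)
    delta[0, 0, 0] = 1.0
    return laplace_hamming_filter(GrayVolume(delta, 1.0), cutoff, laplace_weight).data


def global_threshold(gray: GrayVolume, fraction: float = 0.40) -> BinaryVolume:
    """Binarize at ``fraction`` of the volume's maximal grayscale value.

    Bone is ``intensity >= fraction * max`` (inclusive comparison, so the
    result is deterministic on integer-valued synthetic data). The maximum
    is taken over the whole volume passed in.
    """
    data = np.asarray(gray.data)
    vmax = float(data.max())
    if vmax <= 0:
        raise ValueError("cannot threshold an all-zero (or nonpositive) volume")
    bone = data >= fraction * vmax
    out = BinaryVolume(bone, gray.voxel_size_mm)
    out.meta = dict(getattr(gray, "meta", {}))
    out.meta["global_threshold"] = {"fraction": fraction, "max_gray": vmax}
    return out


def extract_cubic_subvolume(vol, side_voxels: int, center=None):
    """Extract a centered cubic subvolume of ``side_voxels`` per edge.

    ``center=None`` (or ``"auto"``) uses the grid center. The cube must fit
    entirely inside the volume. Physical side = ``side_voxels * voxel_size``.
    """
    shape = vol.data.shape
    if center is None or (isinstance(center, str) and center == "auto"):
        center = tuple(n // 2 for n in shape)
    center = tuple(int(c) for c in center)
    half_lo = side_voxels // 2
    starts = [c - half_lo for c in center]
    for s, n in zip(starts, shape):
        if s < 0 or s + side_voxels > n:
            raise ValueError(
                f"cubic subvolume side={side_voxels} at center={center} does not "
                f"fit inside volume of shape {shape}"
            )
    sl = tuple(slice(s, s + side_voxels) for s in starts)
    cls = type(vol)
    out = cls(vol.data[sl].copy(), vol.voxel_size_mm)
    out.meta = dict(getattr(vol, "meta", {}))
    out.meta["subvolume"] = {"side_voxels": side_voxels, "center_zyx": list(center)}
    return out
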