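"""Volume containers and file I/O.

All arrays use 0-based ``(z, y, x)`` index order internally, with ``z`` the
longitudinal (scan) axis. Readers convert external axis conventions at the
boundary; writers convert back. Voxels must be isotropic — anisotropic
headers are rejected because every downstream measurement (thickness,
length, element size) assumes a single edge length.

Supported formats: NIfTI (``.nii``/``.nii.gz``, via nibabel), MetaImage
(``.mha``/``.mhd``, via SimpleITK), and raw ``uint8`` with a mandatory JSON
sidecar (no header guessing). Metric tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GrayVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "write_metrics",
    "read_metrics",
]

_ISO_RTOL = 1e-3  # relative tolerance when checking voxel isotropy


def _check_voxel_size(voxel_size_mm: float) -> float:
    v = float(voxel_size_mm)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"voxel size must be finite and > 0, got {voxel_size_mm!r}")
    return v


@dataclass
class GrayVolume:
    """3D grayscale volume with isotropic voxel size (mm), axes (z, y, x)."""

    data: np.ndarray
    voxel_size_mm: float
    axes: str = "zyx"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D with all dimensions >= 1")
        self.voxel_size_mm = _check_voxel_size(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_size_mm(self) -> tuple[float, float, float]:
        """Physical side lengths, dimension x voxel size (exact)."""
        return tuple(n * self.voxel_size_mm for n in self.data.shape)


@dataclass
class BinaryVolume:
    """3D boolean volume (True = bone), isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_size_mm: float
    axes: str = "zyx"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D with all dimensions >= 1")
        self.voxel_size_mm = _check_voxel_size(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bv(self) -> int:
        """Bone voxel count."""
        return int(self.data.sum())

    @property
    def tv(self) -> int:
        """Total voxel count."""
        return int(self.data.size)

    @property
    def bv_tv(self) -> float:
        """Bone volume fraction, in [0, 1]."""
        return self.bv / self.tv

    def physical_size_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.data.shape)


def _wrap(data: np.ndarray, voxel: float, binary: bool | None):
    data = np.asarray(data)
    if binary is None:
        vals = np.unique(data)
        binary = bool(np.isin(vals, (0, 1)).all())
    if binary:
        return BinaryVolume(data != 0, voxel)
    return GrayVolume(data, voxel)


def _isotropic(zooms) -> float:
    zooms = np.asarray(zooms, dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=_ISO_RTOL, atol=0):
        raise ValueError(
            f"anisotropic voxels {tuple(zooms)} are not supported: the plate/rod "
            "and micro-FE pipeline assumes isotropic voxels; resample first"
        )
    return _check_voxel_size(zooms[0])


def read_volume(path, format: str | None = None, binary: bool | None = None):
    """Read a volume; returns :class:`BinaryVolume` if values are {0,1} (or
    ``binary=True``), else :class:`GrayVolume`.

    ``format`` is inferred from the extension when omitted
    (``nifti`` | ``metaimage`` | ``raw``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        voxel = _isotropic(img.header.get_zooms()[:3])
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError("only 3D NIfTI volumes are supported")
        return _wrap(np.transpose(data, (2, 1, 0)), voxel, binary)
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        voxel = _isotropic(img.GetSpacing())
        return _wrap(sitk.GetArrayFromImage(img), voxel, binary)
    if fmt == "raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"raw volume {path} requires a JSON sidecar {sidecar.name} "
                "(keys: shape_zyx, dtype, voxel_size_mm)"
            )
        hdr = json.loads(sidecar.read_text())
        shape = tuple(int(n) for n in hdr["shape_zyx"])
        data = np.fromfile(path, dtype=np.dtype(hdr["dtype"])).reshape(shape)
        return _wrap(data, float(hdr["voxel_size_mm"]), binary)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def write_volume(vol, path, format: str | None = None) -> Path:
    """Write a Gray/BinaryVolume (binary is stored as uint8 0/1)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    data = vol.data
    if isinstance(vol, BinaryVolume):
        data = data.astype(np.uint8)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms((vol.voxel_size_mm,) * 3)
        nib.save(img, str(path))
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing((vol.voxel_size_mm,) * 3)
        sitk.WriteImage(img, str(path))
    elif fmt == "raw":
        data = np.ascontiguousarray(data)
        data.tofile(path)
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "shape_zyx": list(data.shape),
                    "dtype": data.dtype.name,
                    "voxel_size_mm": vol.voxel_size_mm,
                }
            )
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_metrics(table: pd.DataFrame, path) -> Path:
    """Write a per-subject metrics table to CSV.

    Floats are written with 17 significant digits so numeric values
    round-trip bit-exactly through text.
    """
    if len(table) == 0:
        raise ValueError("metrics table is empty")
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
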