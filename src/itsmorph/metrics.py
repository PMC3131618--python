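"""ITS morphological parameters of a plate/rod decomposition.

Fourteen individual-trabeculae parameters plus bone volume fraction:

* ``pBV/TV``, ``rBV/TV`` — plate / rod bone volume fractions (their sum is
  BV/TV by construction, since every bone voxel belongs to exactly one
  plate or rod);
* ``aBV/TV`` — axial bone volume fraction: volume of trabeculae aligned
  with the longitudinal (z) axis. A rod is axial when its axis lies within
  ``axial_cone_deg`` of z; a plate when its plane contains z to within the
  same cone (i.e. its normal is at least ``90 - axial_cone_deg`` from z);
* ``pBV/BV``, ``rBV/BV`` — plate / rod tissue fractions (sum to 1);
* ``pTb.N``, ``rTb.N`` — number densities in 1/mm, the cube root of count
  per examined volume (the only reading consistent with the printed unit
  for a count-per-volume quantity);
* ``pTb.Th``, ``rTb.Th`` — bone-volume-weighted mean thickness (mm);
* ``pTb.S`` — mean plate surface area (mm^2); ``rTb.l`` — mean rod length (mm);
* ``R-R/P-R/P-P Junc.D`` — junction densities per mm^3, counted on the
  1-voxel-thick skeleton (one junction = one connected junction cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .decompose import PLATE, ROD, TrabeculaLabelMap

__all__ = ["ITSMetrics", "compute_its_metrics", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "BV/TV",
    "pBV/TV",
    "rBV/TV",
    "aBV/TV",
    "pBV/BV",
    "rBV/BV",
    "pTb.N",
    "rTb.N",
    "pTb.Th",
    "rTb.Th",
    "pTb.S",
    "rTb.l",
    "R-R Junc.D",
    "P-R Junc.D",
    "P-P Junc.D",
]


@dataclass
class ITSMetrics:
    """The 14 ITS parameters plus BV/TV for one volume."""

    bv_tv: float = 0.0
    p_bv_tv: float = 0.0
    r_bv_tv: float = 0.0
    a_bv_tv: float = 0.0
    p_bv_bv: float = 0.0
    r_bv_bv: float = 0.0
    p_tb_n: float = 0.0  # 1/mm
    r_tb_n: float = 0.0  # 1/mm
    p_tb_th: float = 0.0  # mm
    r_tb_th: float = 0.0  # mm
    p_tb_s: float = 0.0  # mm^2, mean area per plate
    r_tb_l: float = 0.0  # mm, mean rod length
    rr_junc_d: float = 0.0  # 1/mm^3
    pr_junc_d: float = 0.0
    pp_junc_d: float = 0.0
    counts: dict = field(default_factory=dict)  # integer bookkeeping

    def as_dict(self) -> dict[str, float]:
        vals = [getattr(self, f.name) for f in fields(self) if f.name != "counts"]
        return dict(zip(METRIC_COLUMNS, vals))


def compute_its_metrics(
    labels: TrabeculaLabelMap,
    tv_voxels: int | None = None,
    voxel_size: float | None = None,
    axial_cone_deg: float = 30.0,
) -> ITSMetrics:
    """Derive the ITS parameter set from a trabecula label map.

    ``tv_voxels`` defaults to the full grid of the label map (the examined
    volume); ``voxel_size`` to the label map's. An empty decomposition
    returns all-zero metrics with a warning.
    """
    h = voxel_size if voxel_size is not None else labels.voxel_size_mm
    tv_vox = int(tv_voxels) if tv_voxels is not None else int(labels.label_map.size)
    if tv_vox <= 0:
        raise ValueError("total volume must be positive")
    tv_mm3 = tv_vox * h**3

    recs = labels.records
    if not recs or sum(r.n_voxels for r in recs) == 0:
        warnings.warn("empty label map: all ITS metrics are zero", stacklevel=2)
        return ITSMetrics(counts={"tv_voxels": tv_vox})

    plates = [r for r in recs if r.type == PLATE]
    rods = [r for r in recs if r.type == ROD]
    p_vox = sum(r.n_voxels for r in plates)
    r_vox = sum(r.n_voxels for r in rods)
    bv = p_vox + r_vox

    cos_cone = np.cos(np.deg2rad(axial_cone_deg))
    a_vox = 0
    for r in recs:
        cz = abs(r.orientation[0])  # |cos(angle to z)|; orientation is (z,y,x)
        axial = cz >= cos_cone if r.type == ROD else cz <= np.sin(np.deg2rad(axial_cone_deg))
        if axial:
            a_vox += r.n_voxels

    m = ITSMetrics()
    m.bv_tv = bv / tv_vox
    m.p_bv_tv = p_vox / tv_vox
    m.r_bv_tv = r_vox / tv_vox
    m.a_bv_tv = a_vox / tv_vox
    m.p_bv_bv = p_vox / bv
    m.r_bv_bv = r_vox / bv
    m.p_tb_n = (len(plates) / tv_mm3) ** (1.0 / 3.0)
    m.r_tb_n = (len(rods) / tv_mm3) ** (1.0 / 3.0)
    if p_vox:
        m.p_tb_th = sum(r.thickness_mm * r.n_voxels for r in plates) / p_vox
    if r_vox:
        m.r_tb_th = sum(r.thickness_mm * r.n_voxels for r in rods) / r_vox
    if plates:
        m.p_tb_s = float(np.mean([r.surface_area_mm2 for r in plates]))
    if rods:
        m.r_tb_l = float(np.mean([r.length_mm for r in rods]))
    jc = labels.junction_counts
    m.rr_junc_d = jc.get("RR", 0) / tv_mm3
    m.pr_junc_d = jc.get("PR", 0) / tv_mm3
    m.pp_junc_d = jc.get("PP", 0) / tv_mm3
    m.counts = {
        "tv_voxels": tv_vox,
        "plate_voxels": p_vox,
        "rod_voxels": r_vox,
        "axial_voxels": a_vox,
        "n_plates": len(plates),
        "n_rods": len(rods),
        **{k: int(v) for k, v in jc.items()},
    }
    return m
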