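"""Estimate apparent orthotropic elastic constants by voxel micro-FE.

Each bone voxel becomes an 8-node brick element (tissue E = 15 GPa,
nu = 0.3); six kinematic uniform-strain load cases give the 6x6 apparent
stiffness, a Powell search finds the best orthotropic axes, and the sorted
engineering constants E11 <= E22 <= E33 are reported.
"""

import numpy as np

from itsmorph import generate_phantom, homogenize, make_trabecular_phantom

spec = make_trabecular_phantom(seed=7, shape=32)
volume, _ = generate_phantom(spec)
print(f"model: {volume.bv} brick elements at {volume.voxel_size_mm} mm")

result = homogenize(volume)
c = result.constants
print(f"orthotropy objective at optimum: {result.orthotropy_objective:.2e}")
for k in ("E11", "E22", "E33", "G23", "G31", "G12"):
    print(f"  {k} = {c[k]*1000:7.1f} MPa")
ratio = c["E33"] / c["E11"]
print(
    f"\nE33/E11 = {ratio:.2f}: the longitudinal (z) direction is stiffest, as\n"
    "expected for a vertically organized trabecular network; the ratio is\n"
    "independent of the tissue modulus (all moduli scale linearly in E_t)."
)
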