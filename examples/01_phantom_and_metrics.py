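"""Build a synthetic trabecular volume and measure its plate/rod morphology.

The phantom is a jittered strut network with a few vertical plates at
82 um voxels, mimicking a peripheral-site trabecular cube. Every bone
voxel is assigned to one individual plate or rod, and the ITS parameter
set is printed.
"""

from itsmorph import compute_its_metrics, decompose, generate_phantom, make_trabecular_phantom

spec = make_trabecular_phantom(seed=7, shape=48)
volume, truth = generate_phantom(spec)
print(f"phantom: {volume.shape} voxels, BV/TV = {volume.bv_tv:.3f}, "
      f"{truth.n_plates} plates + {truth.n_rods} rod struts generated")

labels = decompose(volume)
n_plate = sum(1 for r in labels.records if r.type == "plate")
n_rod = len(labels.records) - n_plate
print(f"decomposition: {n_plate} plates, {n_rod} rods, junctions {labels.junction_counts}")

metrics = compute_its_metrics(labels)
for name, value in metrics.as_dict().items():
    print(f"  {name:12s} {value:8.4f}")

print(
    "\npBV/TV + rBV/TV equals BV/TV exactly (every bone voxel belongs to one\n"
    "trabecula); rTb.N is the cube root of rods per volume (1/mm); thickness\n"
    "and length are in mm, junction densities in 1/mm^3."
)
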