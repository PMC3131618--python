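"""Small intact-vs-degraded cohort and the statistical battery.

Degradation removes whole trabeculae at random (survivor thickness
untouched). The Mann-Whitney comparison shows fewer rods and junctions at
unchanged plate thickness — the signature of trabecular dropout rather
than thinning.
"""

from itsmorph.pipeline import simulate_cohort
from itsmorph.stats import group_percent_difference, mann_whitney_u

table = simulate_cohort(n_per_group=6, shape=40, dropout_p=0.25, seed=3)
intact = table[table["group"] == "intact"]
degraded = table[table["group"] == "degraded"]

for col in ("BV/TV", "rTb.N", "P-R Junc.D", "pTb.Th", "rTb.Th"):
    U, p = mann_whitney_u(intact[col], degraded[col])
    pct = group_percent_difference(intact[col].mean(), degraded[col].mean(), "lower")
    print(f"  {col:12s} intact {intact[col].mean():7.3f}  degraded "
          f"{degraded[col].mean():7.3f}  ({pct:+3d}% lower)  p = {p:.4f}")

print(
    "\nRod number and junction density drop significantly while plate\n"
    "thickness stays flat: the network lost trabeculae, it did not thin them.\n"
    "(Rod thickness can drift by a percent or two because removing crossings\n"
    "also removes locally thicker junction material.)"
)
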