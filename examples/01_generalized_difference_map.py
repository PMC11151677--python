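"""Generalized difference map between two poorly isomorphous datasets.

Builds a synthetic crystal pair in which the ON state differs from the OFF
state by a moved three-atom cluster (the interesting signal) plus a 2%
cell stretch, a 2-degree rotation and a ~1 A translation (uninteresting
packing changes), then computes the rigid-body-phased, real-space-aligned
difference map and reports where its strongest peaks fall.
"""

import numpy as np

from diffmapkit import matchmaps_run, orth_to_frac
from diffmapkit.synthetic_fixtures import FixtureSpec, make_fixture

shift = (3.0, 1.5, 1.2)
moved = [8, 9, 10]
spec = FixtureSpec(seed=11, n_atoms=80, cell_strain=(0.0, 2.0, 0.0),
                   rotation_deg=2.0, translation=(0.7, 0.5, 0.4),
                   cluster_moved=True,
                   displacements=[(i, shift) for i in moved])
fx = make_fixture(spec)

dmap, report = matchmaps_run(fx.structure_off, fx.reflections_off,
                             fx.reflections_on)

overlay = report.stages["overlay"]["pose"]
print(f"recovered overlay rotation: {overlay['angle_deg']:.2f} deg "
      f"(2.00 deg was simulated)")
print(f"ON-refinement amplitude R: "
      f"{report.stages['refine_on']['r_initial']:.3f} -> "
      f"{report.stages['refine_on']['r_final']:.3f}")

cell = fx.structure_off.cell
n = np.array(dmap.shape)
pos_peak = np.unravel_index(np.argmax(dmap.values), dmap.shape)
neg_peak = np.unravel_index(np.argmin(dmap.values), dmap.shape)
new_site = orth_to_frac(cell, fx.structure_off.xyz_orth[moved[0]]
                        + np.array(shift))
print(f"strongest positive peak: {dmap.values[pos_peak]:+.1f} sigma at "
      f"fractional {np.round(np.array(pos_peak) / n, 3)}")
print(f"  (moved cluster's new site is at {np.round(new_site % 1.0, 3)})")
print(f"strongest negative peak: {dmap.values[neg_peak]:+.1f} sigma")
print("positive = density present in ON but not OFF; the +/- pair marks "
      "the cluster's new/old positions despite the cell change.")
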