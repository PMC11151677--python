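"""Classical isomorphous difference map vs the generalized map.

On a strictly isomorphous pair (identical cells, identical orientation)
both maps localize a moved sulfur atom.  Adding a 2% cell stretch, a
2-degree rotation and a ~1 A translation -- packing changes with no
structural meaning -- breaks the classical map's localization while the
generalized map still points at the moved atom.
"""

import numpy as np

from diffmapkit import frac_to_orth, isomorphous_run, matchmaps_run, orth_to_frac
from diffmapkit.structure_factors import _sym_ops
from diffmapkit.synthetic_fixtures import FixtureSpec, make_fixture

SHIFT = np.array([2.5, 1.0, 0.8])
MOVED = 8  # the sulfur


def peak_distance(dmap, sign, site_frac, structure):
    """Distance (A) from the top +/- peak to the nearest symmetry image
    of a site."""
    cell = structure.cell
    sites = np.vstack([(site_frac @ rot.T + tran) % 1.0
                       for rot, tran in _sym_ops(structure.sg)])
    idx = np.unravel_index(np.argmax(sign * dmap.values), dmap.shape)
    pf = np.array(idx) / np.array(dmap.shape)
    d = (pf - sites + 0.5) % 1.0 - 0.5
    return np.min(np.linalg.norm(frac_to_orth(cell, d), axis=1))


for label, extra in [("isomorphous pair (same cell, same orientation)", {}),
                     ("poorly isomorphous pair (+2% cell, 2 deg, 1 A)",
                      dict(cell_strain=(0.0, 2.0, 0.0), rotation_deg=2.0,
                           translation=(0.7, 0.5, 0.4)))]:
    fx = make_fixture(FixtureSpec(seed=4, n_atoms=40,
                                  displacements=[(MOVED, tuple(SHIFT))],
                                  **extra))
    off = fx.structure_off
    old = off.xyz_frac[[MOVED]]
    new = orth_to_frac(off.cell, off.xyz_orth[[MOVED]] + SHIFT)
    mm, _ = matchmaps_run(off, fx.reflections_off, fx.reflections_on)
    iso, _ = isomorphous_run(off, fx.reflections_off, fx.reflections_on)
    print(label + ":")
    print(f"  generalized map: +peak {peak_distance(mm, +1, new, off):.2f} A "
          f"from the atom's new site, -peak "
          f"{peak_distance(mm, -1, old, off):.2f} A from its old site")
    print(f"  classical map:   +peak {peak_distance(iso, +1, new, off):.2f} A "
          f"from the new site, -peak "
          f"{peak_distance(iso, -1, old, off):.2f} A from the old site")
print("\n(grid step is 0.67 A: a distance below ~0.7 A means the peak "
      "sits on the true site; several angstroms means the map's "
      "strongest feature is a packing artifact.)")
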