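"""Difference map between two different crystal forms.

The same molecule is built into a P1 cell (OFF) and a P2_1 cell (ON, with
one atom moved 1.7 A).  Given an externally supplied placement of the OFF
model in the ON form -- the role a molecular-replacement program plays for
real data -- the cross-form difference map localizes the moved atom.
"""

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from diffmapkit import (Pose, ReflectionSet, Structure, fcalc_direct,
                        full_hkl_list, matchmaps_mr, orth_to_frac,
                        spacegroup)

rng = np.random.default_rng(9)
cell_off = gemmi.UnitCell(30, 34, 40, 90, 90, 90)
n = 14
elements = ["C", "C", "C", "N", "N", "O", "O", "O", "S", "C", "N", "O",
            "C", "N"]
frac = 0.2 + 0.14 * rng.random((n, 3))
st_off = Structure(elements, frac, 10 + 5 * rng.random(n), np.ones(n),
                   ["A"] * n, np.arange(1, n + 1), cell_off,
                   spacegroup("P 1"))


def amplitudes(st):
    hkl = full_hkl_list(st.cell, st.sg, 2.0)
    f = np.abs(fcalc_direct(st, hkl))
    keep = f > 1e-8
    return ReflectionSet(pd.DataFrame({"H": hkl[keep, 0], "K": hkl[keep, 1],
                                       "L": hkl[keep, 2], "F": f[keep]}),
                         st.cell, st.sg)


refl_off = amplitudes(st_off)

cell_on = gemmi.UnitCell(36, 30, 38, 90, 90, 90)
axis = rng.normal(size=3)
axis /= np.linalg.norm(axis)
rot = Rotation.from_rotvec(np.radians(25.0) * axis).as_matrix()
placement = Pose(rot, np.array([4.0, -2.0, 3.0]),
                 st_off.xyz_orth.mean(axis=0))
orth_on = placement.apply(st_off.xyz_orth)
disp = np.array([1.6, 0.5, 0.4])
orth_on[4] += disp
truth = Structure(elements, orth_to_frac(cell_on, orth_on), st_off.b_iso,
                  np.ones(n), ["A"] * n, np.arange(1, n + 1), cell_on,
                  spacegroup("P 1 21 1"))
refl_on = amplitudes(truth)

dmap, report = matchmaps_mr(st_off, refl_off, refl_on, placement=placement)


def value_at(frac_pos):
    grid = np.array(dmap.shape)
    return ndimage.map_coordinates(
        dmap.values, (np.asarray(frac_pos) % 1.0 * grid)[:, None],
        order=1, mode="grid-wrap")[0]


old_site = st_off.xyz_frac[4]
new_site = orth_to_frac(cell_off, st_off.xyz_orth[4] + rot.T @ disp)
print(f"crystal forms: OFF {refl_off.sg.hm} {cell_off.a:g} A cell; "
      f"ON {refl_on.sg.hm} {cell_on.a:g} A cell")
print(f"cross-form scale fitted: k = "
      f"{report.stages['scaling']['scale']['k']:.3f} (1.0 expected)")
print(f"difference density at the atom's old site: {value_at(old_site):+.1f} "
      f"sigma (density lost in the ON form)")
print(f"difference density at its new site:       {value_at(new_site):+.1f} "
      f"sigma (density gained)")
print("the moved atom is resolved across space groups; the ON model was "
      "never built, only a placement was supplied.")
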