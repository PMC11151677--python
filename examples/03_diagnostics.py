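"""Quantifying (non-)isomorphism between two datasets.

Compares an unstrained pair against a +2%-strained pair of the same toy
crystal: binned amplitude correlations, the phase figure of merit
<cos(delta phi)>, the global R_iso and the amplitude-vs-phase-difference
violation score.
"""

import numpy as np
import pandas as pd

from diffmapkit import (ReflectionSet, fcalc_direct, isomorphism_report)
from diffmapkit.synthetic_fixtures import FixtureSpec, make_fixture


def with_calc_phases(fx, structure):
    """Attach exact calculated phases so phase statistics are available."""
    hkl = fx.reflections_off.hkl
    f = fcalc_direct(structure, hkl)
    df = pd.DataFrame({"H": hkl[:, 0], "K": hkl[:, 1], "L": hkl[:, 2],
                       "F": np.abs(f),
                       "PHI": np.degrees(np.angle(f))})
    return ReflectionSet(df, structure.cell, structure.sg)


for label, strain in [("unstrained", (0.0, 0.0, 0.0)),
                      ("+2% on b", (0.0, 2.0, 0.0))]:
    fx = make_fixture(FixtureSpec(seed=0, noise=0.02, cell_strain=strain))
    set1 = with_calc_phases(fx, fx.structure_off)
    set2 = with_calc_phases(fx, fx.structure_on_truth)
    report = isomorphism_report(set1, set2, n_bins=8, prescale=False)
    high_res = report.bins.iloc[-1]
    print(f"{label}:")
    print(f"  R_iso = {report.r_iso:.3f}; "
          f"violation score = {report.violation_score:.4f}")
    print(f"  highest-resolution bin (d ~ {high_res['d_mean']:.2f} A): "
          f"CC(|F|) = {high_res['cc_amp']:.3f}, "
          f"FOM = {high_res['fom']:.3f}")
print("\nA FOM near 1 means one set of phases serves both datasets (the "
      "premise of the classical difference map); strain drives the "
      "high-resolution FOM down and the violation score up.")
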