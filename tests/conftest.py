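import gemmi
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diffmapkit import ReflectionSet, Structure, spacegroup
from diffmapkit.synthetic_fixtures import FixtureSpec, make_fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def p1_cell():
    return gemmi.UnitCell(30.0, 34.0, 40.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def small_p1_structure(p1_cell):
    """5 atoms in P1 for cheap exact structure-factor checks."""
    rng = np.random.default_rng(42)
    elems = ["C", "N", "O", "S", "C"]
    frac = 0.15 + 0.2 * rng.random((5, 3))
    return Structure(elems, frac, 8.0 + 6.0 * rng.random(5), np.ones(5),
                     ["A"] * 5, np.arange(1, 6), p1_cell, spacegroup("P 1"))


@pytest.fixture(scope="session")
def default_fixture():
    """Unperturbed 12-atom P2_1 2_1 2_1 crystal (self-consistency tests)."""
    return make_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def posed_fixture():
    """3 deg / 1.5 A rigid perturbation, no noise."""
    return make_fixture(FixtureSpec(seed=7, rotation_deg=3.0,
                                    translation=(0.9, -0.9, 0.6)))


def reflections_from(structure, d_min=2.0, sigf_frac=0.02):
    from diffmapkit import fcalc_direct, full_hkl_list
    hkl = full_hkl_list(structure.cell, structure.sg, d_min)
    f = np.abs(fcalc_direct(structure, hkl))
    keep = f > 1e-8
    df = pd.DataFrame({"H": hkl[keep, 0], "K": hkl[keep, 1],
                       "L": hkl[keep, 2], "F": f[keep]})
    if sigf_frac:
        df["SIGF"] = np.maximum(sigf_frac * df["F"], 1e-6)
    return ReflectionSet(df, structure.cell, structure.sg)
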