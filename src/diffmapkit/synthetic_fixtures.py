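"""Toy crystals and simulated observed amplitudes for testing.

Every pipeline stage in this package is exercised on synthetic fixtures: a
small cluster of atoms in a P1 / P2_1 / C2 / P2_1 2_1 2_1 cell, with the ON
state derived from the OFF state by a controlled perturbation -- a rigid
pose, a per-axis cell strain, individual atom displacements, added or
removed atoms -- and optional multiplicative Gaussian amplitude noise.
Observed amplitudes are exact direct-summation structure factors of the
(perturbed) model, so ground truth is known by construction and nothing
needs to be downloaded.

The ON truth structure is returned for test assertions only; the pipeline
itself never sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .crystal_core import ReflectionSet, Structure, spacegroup
from .rigid_body import Pose, apply_pose
from .structure_factors import fcalc_direct, full_hkl_list

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "default_structure"]

_DEFAULT_ELEMENTS = ["C", "C", "C", "N", "N", "O", "O", "O", "S", "C", "N", "O"]


@dataclass
class FixtureSpec:
    """Recipe for a reproducible synthetic crystal pair.

    Defaults: 12 atoms (C/N/O/S mix) clustered in a 30 x 34 x 40 A
    orthorhombic cell, P2_1 2_1 2_1, data to 2.0 A -- large enough for
    stable scaling and refinement, small enough for seconds-scale direct
    summation.
    """

    cell: tuple[float, float, float, float, float, float] = (30.0, 34.0, 40.0,
                                                             90.0, 90.0, 90.0)
    spacegroup: str = "P 21 21 21"
    n_atoms: int = 12
    elements: list[str] | None = None
    d_min: float = 2.0
    # ON-state perturbations
    rotation_deg: float = 0.0
    rotation_axis: tuple[float, float, float] | None = None
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cell_strain: tuple[float, float, float] = (0.0, 0.0, 0.0)  # % per axis
    displacements: list[tuple[int, tuple[float, float, float]]] = field(
        default_factory=list)  # (atom index, orth shift in A)
    cluster_moved: bool = False  # co-locate displaced atoms as a compact triad
    added_atoms: list[tuple[str, tuple[float, float, float]]] = field(
        default_factory=list)  # (element, fractional position in ON cell)
    removed_atoms: list[int] = field(default_factory=list)
    noise: float = 0.0  # relative Gaussian sigma on ON amplitudes
    sigf_frac: float = 0.02  # reported sigma(F)/F for both datasets
    seed: int = 0


@dataclass
class Fixture:
    """A generated crystal pair; ``structure_on_truth`` is for assertions only."""

    structure_off: Structure
    reflections_off: ReflectionSet
    structure_on_truth: Structure
    reflections_on: ReflectionSet
    true_pose: Pose
    spec: FixtureSpec


def default_structure(spec: FixtureSpec, rng: np.random.Generator) -> Structure:
    """Compact random atom cluster occupying ~1/8 of the cell."""
    elements = spec.elements or [
        _DEFAULT_ELEMENTS[i % len(_DEFAULT_ELEMENTS)] for i in range(spec.n_atoms)]
    n = len(elements)
    frac = 0.18 + 0.16 * rng.random((n, 3))
    b = 8.0 + 8.0 * rng.random(n)
    occ = np.ones(n)
    return Structure(elements, frac, b, occ, ["A"] * n, np.arange(1, n + 1),
                     gemmi.UnitCell(*spec.cell), spacegroup(spec.spacegroup))


def _amplitudes(model: Structure, d_min: float, noise: float,
                sigf_frac: float, rng: np.random.Generator) -> ReflectionSet:
    hkl = full_hkl_list(model.cell, model.sg, d_min)
    f = np.abs(fcalc_direct(model, hkl))
    if noise > 0:
        f = np.clip(f * (1.0 + noise * rng.standard_normal(len(f))), 0.0, None)
    keep = f > 0
    df = pd.DataFrame({"H": hkl[keep, 0], "K": hkl[keep, 1], "L": hkl[keep, 2],
                       "F": f[keep]})
    df["SIGF"] = np.maximum(sigf_frac * df["F"], 1e-6)
    return ReflectionSet(df, model.cell, model.sg)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the OFF/ON crystal pair described by ``spec``.

    The ON truth is built from the OFF structure by (in order) applying
    atom displacements/additions/removals, straining the cell (orthogonal
    coordinates re-fractionalized into the strained cell after scaling
    with the lattice, i.e. fractional coordinates are preserved under
    strain), and applying the rigid pose.  Identical spec + seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    off = default_structure(spec, rng)
    if spec.cluster_moved and spec.displacements:
        # gather the atoms that will move into a bonded-like cluster around
        # the first of them (side-chain mimic: ~1.2 A spacing)
        idx = [i for i, _ in spec.displacements]
        orth = off.xyz_orth.copy()
        anchor = orth[idx[0]].copy()
        offsets = np.array([[0.0, 0.0, 0.0], [1.2, 0.5, 0.0],
                            [0.4, 1.2, 0.6], [-0.9, 0.8, 0.7]])
        for rank, i in enumerate(idx):
            orth[i] = anchor + offsets[rank % len(offsets)]
        off = off.with_orth_coords(orth)
    refl_off = _amplitudes(off, spec.d_min, 0.0, spec.sigf_frac, rng)

    # internal perturbations first (these are the "interesting" signal)
    truth = replace(off)
    truth.xyz_frac = off.xyz_frac.copy()
    if spec.removed_atoms:
        keep = np.setdiff1d(np.arange(len(truth)), np.array(spec.removed_atoms))
        truth = truth.select(np.isin(np.arange(len(truth)), keep))
    orth = truth.xyz_orth.copy()
    for idx, shift in spec.displacements:
        orth[idx] = orth[idx] + np.asarray(shift, dtype=float)
    truth = truth.with_orth_coords(orth)

    # cell strain: the molecule stays rigid (orthogonal geometry preserved)
    # while the lattice changes; its centroid keeps its fractional position,
    # emulating solvent-dominated cell changes around an unchanged molecule
    strain = np.asarray(spec.cell_strain, dtype=float) / 100.0
    if np.any(strain != 0):
        c = truth.cell
        new_cell = gemmi.UnitCell(c.a * (1 + strain[0]), c.b * (1 + strain[1]),
                                  c.c * (1 + strain[2]), c.alpha, c.beta, c.gamma)
        if new_cell.volume <= 0:
            raise ValueError("cell strain makes the cell invalid")
        centroid_frac = truth.xyz_frac.mean(axis=0)
        truth = truth.with_cell(new_cell)
        truth.xyz_frac = truth.xyz_frac + (centroid_frac - truth.xyz_frac.mean(axis=0))

    if spec.added_atoms:
        for elem, fpos in spec.added_atoms:
            truth = Structure(
                truth.elements + [elem],
                np.vstack([truth.xyz_frac, np.asarray(fpos, dtype=float)]),
                np.append(truth.b_iso, 12.0), np.append(truth.occ, 1.0),
                truth.chain_ids + ["A"],
                np.append(truth.res_seq, truth.res_seq.max() + 1),
                truth.cell, truth.sg)

    # rigid pose (the "uninteresting" packing signal the pipeline removes)
    if spec.rotation_deg != 0.0 or np.any(np.asarray(spec.translation) != 0):
        axis = np.asarray(spec.rotation_axis if spec.rotation_axis is not None
                          else rng.normal(size=3), dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(spec.rotation_deg) * axis).as_matrix()
        center = truth.xyz_orth.mean(axis=0)
        pose = Pose(rot, np.asarray(spec.translation, dtype=float), center)
        truth = apply_pose(truth, pose)
    else:
        pose = Pose.identity(truth.xyz_orth.mean(axis=0))

    refl_on = _amplitudes(truth, spec.d_min, spec.noise, spec.sigf_frac, rng)
    return Fixture(off, refl_off, truth, refl_on, pose, spec)
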